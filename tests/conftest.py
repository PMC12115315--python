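"""Shared fixtures: small seeded libraries and FASTQ helpers."""

from __future__ import annotations

import io
from itertools import combinations

import pytest

from amirscreen import generate_library
from amirscreen.sequencing import write_fastq


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="session")
def tiny_library():
    """Six neutral clones with 8-nt guides."""
    return generate_library(6, 8, seed=7)


@pytest.fixture(scope="session")
def spaced_library():
    """60 clones whose guides are pairwise Hamming > 4.

    Guarantees that error-free guides can never be merged by clustering at
    any radius up to 2, so family recovery is unambiguous.
    """
    lib = generate_library(60, 22, seed=11)
    min_d = min(hamming(a, b) for a, b in combinations(lib.guides, 2))
    assert min_d > 4, "fixture guides must be pairwise Hamming > 4"
    return lib


def fastq_io(reads: list[str]) -> io.StringIO:
    """In-memory FASTQ stream for a list of read sequences."""
    buf = io.StringIO()
    write_fastq(reads, buf)
    buf.seek(0)
    return buf
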