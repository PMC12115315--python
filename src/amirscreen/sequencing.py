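"""Synthetic amplicon sequencing of pooled virus populations.

Each read is the full amplicon ``backbone5 + guide + backbone3`` for a
template clone drawn multinomially from the pool's frequencies, with i.i.d.
per-base substitution errors (no indels) and a constant Phred+33 quality
string of 'I' (Q40).  The per-read template ledger is returned so that
downstream error correction can be validated against the simulation truth.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .library import AmiRNALibrary, amplicon
from .passage import PoolState

__all__ = ["SeqParams", "emit_reads", "simulate_reads", "write_fastq"]

QUALITY_CHAR = "I"  # Phred+33 encoding of Q40

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i

_CHUNK = 50_000  # reads processed per vectorized block


@dataclass(frozen=True)
class SeqParams:
    """Sequencing run parameters: reads per sample, substitution rate, seed."""

    depth: int
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")


def simulate_reads(
    pool: PoolState,
    library: AmiRNALibrary,
    params: SeqParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    """Draw ``depth`` reads; returns (reads, template clone index per read).

    Same seed (or generator state) always yields the identical read list.
    """
    if pool.total <= 0:
        raise ValueError("cannot sequence an empty pool")
    if pool.clone_ids != library.clone_ids:
        raise ValueError("pool and library clone sets differ")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    freqs = pool.frequencies
    templates = np.vstack(
        [
            _CODE_OF[np.frombuffer(amplicon(library, g).encode("ascii"), dtype=np.uint8)]
            for g in library.guides
        ]
    )
    read_len = templates.shape[1]
    idx = rng.choice(library.n_clones, size=params.depth, p=freqs)
    reads: list[str] = []
    for start in range(0, params.depth, _CHUNK):
        block = idx[start : start + _CHUNK]
        arr = templates[block].copy()
        if params.error_rate > 0:
            mask = rng.random(arr.shape) < params.error_rate
            n_err = int(mask.sum())
            if n_err:
                # substitute with one of the three other bases, uniformly
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                arr[mask] = (arr[mask] + shift) % 4
        raw = _BASE_CODES[arr].tobytes()
        reads.extend(
            raw[i * read_len : (i + 1) * read_len].decode("ascii")
            for i in range(len(block))
        )
    return reads, idx


def write_fastq(
    reads: list[str],
    out: str | Path | io.TextIOBase,
    *,
    read_prefix: str = "read",
) -> None:
    """Write reads as single-end FASTQ (Phred+33, constant Q40 qualities).

    ``out`` may be a path (gzip-compressed when it ends in ``.gz``) or an
    open text handle.
    """
    if isinstance(out, (str, Path)):
        path = Path(out)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as handle:  # type: ignore[operator]
            write_fastq(reads, handle, read_prefix=read_prefix)
        return
    for i, seq in enumerate(reads):
        out.write(f"@{read_prefix}:{i}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")


def emit_reads(
    pool: PoolState,
    library: AmiRNALibrary,
    params: SeqParams,
    out: str | Path | io.TextIOBase,
    *,
    read_prefix: str = "read",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a sample's FASTQ and write it to ``out``.

    Returns the template ledger: the clone index each read was drawn from
    (simulation ground truth, not part of the FASTQ itself).
    """
    reads, idx = simulate_reads(pool, library, params, rng=rng)
    write_fastq(reads, out, read_prefix=read_prefix)
    return idx
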