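"""Anchor-based guide extraction from amplicon reads.

Reads carry the guide between two constant backbone flanks.  Extraction
locates each flank with a tolerated number of mismatches (substitutions
only, no indels) and returns the intervening substring when its length is
within tolerance of the expected guide length.  Reads failing either anchor
or the length check are dropped, never clustered.
"""

from __future__ import annotations

import io
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ExtractionConfig",
    "RawCountTable",
    "assignment_rate",
    "count_raw",
    "extract_guide",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Backbone anchors and matching tolerances for guide extraction."""

    backbone5: str
    backbone3: str
    max_anchor_mm: int = 1
    guide_len: int = 22
    len_tolerance: int = 0

    def __post_init__(self) -> None:
        if not self.backbone5 or not self.backbone3:
            raise ValueError("backbone anchors must be non-empty")
        if self.max_anchor_mm < 0:
            raise ValueError("max_anchor_mm must be >= 0")
        if self.max_anchor_mm >= min(len(self.backbone5), len(self.backbone3)):
            raise ValueError("max_anchor_mm must be smaller than each anchor length")
        if self.guide_len < 1:
            raise ValueError("guide_len must be >= 1")
        if self.len_tolerance < 0:
            raise ValueError("len_tolerance must be >= 0")


def _mismatches_within(read: str, anchor: str, pos: int, limit: int) -> bool:
    """True when ``anchor`` matches ``read`` at ``pos`` with <= limit mismatches."""
    d = 0
    for i, ch in enumerate(anchor):
        if read[pos + i] != ch:
            d += 1
            if d > limit:
                return False
    return True


def extract_guide(read: str, config: ExtractionConfig) -> str | None:
    """Extract the guide from one read, or ``None`` when no valid layout exists.

    The 5' anchor is placed at the leftmost position matching with at most
    ``max_anchor_mm`` mismatches; for that position, the leftmost matching 3'
    anchor yielding a guide length within ``guide_len +/- len_tolerance``
    wins.  If no 3' placement works the next 5' position is tried.
    """
    if not read:
        raise ValueError("read must be non-empty")
    b5, b3 = config.backbone5, config.backbone3
    n5, n3 = len(b5), len(b3)
    mm = config.max_anchor_mm
    gmin = max(config.guide_len - config.len_tolerance, 0)
    gmax = config.guide_len + config.len_tolerance
    for p5 in range(0, len(read) - n5 + 1):
        if not _mismatches_within(read, b5, p5, mm):
            continue
        guide_start = p5 + n5
        for gap in range(gmin, gmax + 1):
            p3 = guide_start + gap
            if p3 + n3 > len(read):
                break
            if _mismatches_within(read, b3, p3, mm):
                return read[guide_start:p3]
    return None


@dataclass(frozen=True)
class RawCountTable:
    """Per-sample tally of distinct extracted guide sequences."""

    sample_id: str
    counts: dict[str, int]
    n_reads_total: int
    n_reads_assigned: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("all counts must be positive")
        if sum(self.counts.values()) != self.n_reads_assigned:
            raise ValueError("n_reads_assigned must equal the sum of counts")
        if self.n_reads_assigned > self.n_reads_total:
            raise ValueError("assigned reads cannot exceed total reads")

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["sequence", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _iter_fastq(
    fastq: str | Path | io.TextIOBase | Iterable[tuple[str, str, str]],
) -> Iterator[tuple[str, str, str]]:
    if isinstance(fastq, (str, Path)):
        with open(fastq) as handle:
            yield from FastqGeneralIterator(handle)
    elif isinstance(fastq, io.TextIOBase):
        yield from FastqGeneralIterator(fastq)
    else:
        yield from fastq


def count_raw(
    fastq: str | Path | io.TextIOBase | Iterable[tuple[str, str, str]],
    config: ExtractionConfig,
    sample_id: str = "sample",
) -> RawCountTable:
    """Tally extracted guides over a FASTQ stream.

    ``fastq`` may be a path, an open text handle, or an iterable of
    ``(title, sequence, quality)`` records.  Malformed FASTQ raises a
    ``ValueError`` naming the offending record index.  Deterministic for a
    given input.
    """
    b5, b3 = config.backbone5, config.backbone3
    n5, n3 = len(b5), len(b3)
    mm = config.max_anchor_mm
    # Fast path for the canonical fixed layout (only valid with zero length
    # tolerance): anchors at positions 0 and L - n3.  When it succeeds it
    # agrees exactly with extract_guide, whose leftmost-anchor rule would
    # pick position 0 and the single admissible 3' placement.
    fixed_len = n5 + config.guide_len + n3 if config.len_tolerance == 0 else -1
    counts: Counter[str] = Counter()
    n_total = 0
    records = _iter_fastq(fastq)
    while True:
        try:
            record = next(records, None)
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record at index {n_total}: {exc}"
            ) from exc
        if record is None:
            break
        seq = record[1]
        n_total += 1
        guide = None
        if len(seq) == fixed_len:
            p3 = fixed_len - n3
            if (seq.startswith(b5) or _mismatches_within(seq, b5, 0, mm)) and (
                seq.endswith(b3) or _mismatches_within(seq, b3, p3, mm)
            ):
                guide = seq[n5:p3]
        if guide is None:
            guide = extract_guide(seq, config)
        if guide is not None:
            counts[guide] += 1
    return RawCountTable(
        sample_id=sample_id,
        counts=dict(counts),
        n_reads_total=n_total,
        n_reads_assigned=sum(counts.values()),
    )


def assignment_rate(raw: RawCountTable) -> float:
    """Fraction of reads from which a guide was extracted."""
    if raw.n_reads_total == 0:
        raise ValueError("assignment rate undefined: no reads were seen")
    return raw.n_reads_assigned / raw.n_reads_total


def qc_summary(raw: RawCountTable) -> dict:
    """QC metrics for one sample, JSON-serializable."""
    return {
        "sample_id": raw.sample_id,
        "n_reads_total": raw.n_reads_total,
        "n_reads_assigned": raw.n_reads_assigned,
        "n_distinct_sequences": len(raw.counts),
        "assignment_rate": assignment_rate(raw) if raw.n_reads_total else None,
    }


def write_qc(tables: Iterable[RawCountTable], path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump([qc_summary(t) for t in tables], handle, indent=2)
        handle.write("\n")
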