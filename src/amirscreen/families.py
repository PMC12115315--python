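"""Error-tolerant collapsing of observed guide sequences into families.

Sequencing errors scatter each true guide into a cloud of low-count
variants.  Families are rebuilt with the directional count-ratio rule used
for amplicon tag data: process distinct sequences in descending count order
(ties lexicographic); sequence ``b`` is absorbed into an existing family
with representative ``a`` iff ``Hamming(a, b) <= d_max`` and
``count(a) >= 2*count(b) - 1``.  When several families qualify, the one
whose representative has the largest count wins (ties: lexicographically
smallest representative).  Otherwise ``b`` founds a new family.  Sequences
of unequal length are never merged (Hamming distance is undefined across
lengths), and absorbed members never recruit further members, so true
neighboring guides are not chained together.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .extraction import RawCountTable
from .library import ALPHABET

__all__ = ["FamilyAssignment", "FamilyCountTable", "cluster_families"]


@dataclass(frozen=True)
class FamilyAssignment:
    """Mapping of every observed sequence to its family representative."""

    representative: dict[str, str]
    families: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "representative", dict(self.representative))
        object.__setattr__(
            self, "families", {r: frozenset(m) for r, m in self.families.items()}
        )


@dataclass(frozen=True)
class FamilyCountTable:
    """Per-sample counts after error collapsing, keyed by representative."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("all family counts must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["representative", "count"])


def _hamming_le(a: str, b: str, limit: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def _neighbor_candidates(seq: str, rep_count: dict[str, int]) -> set[str]:
    """Existing representatives within Hamming distance 1 of ``seq``."""
    found = set()
    for i, ch in enumerate(seq):
        prefix, suffix = seq[:i], seq[i + 1 :]
        for base in ALPHABET:
            if base != ch:
                v = prefix + base + suffix
                if v in rep_count:
                    found.add(v)
    return found


def cluster_families(
    raw: RawCountTable, d_max: int = 1
) -> tuple[FamilyAssignment, FamilyCountTable]:
    """Collapse a raw count table into families (see module docstring).

    ``d_max = 1`` uses O(L) neighborhood lookups per sequence; larger radii
    fall back to scanning representatives of equal length.  Family counts sum
    exactly to the assigned read count of ``raw``.
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    items = sorted(raw.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rep_count: dict[str, int] = {}
    fam_counts: dict[str, int] = {}
    representative: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    reps_by_len: dict[int, list[str]] = defaultdict(list)
    for seq, count in items:
        best = None
        if d_max >= 1 and rep_count:
            if d_max == 1:
                candidates = _neighbor_candidates(seq, rep_count)
            else:
                candidates = {
                    a
                    for a in reps_by_len[len(seq)]
                    if a != seq and _hamming_le(a, seq, d_max)
                }
            eligible = [a for a in candidates if rep_count[a] >= 2 * count - 1]
            if eligible:
                best = min(eligible, key=lambda a: (-rep_count[a], a))
        if best is None:
            rep_count[seq] = count
            fam_counts[seq] = count
            representative[seq] = seq
            members[seq] = {seq}
            reps_by_len[len(seq)].append(seq)
        else:
            representative[seq] = best
            members[best].add(seq)
            fam_counts[best] += count
    assignment = FamilyAssignment(representative, {r: frozenset(m) for r, m in members.items()})
    table = FamilyCountTable(sample_id=raw.sample_id, counts=fam_counts)
    return assignment, table


def family_table_to_tsv(
    assignment: FamilyAssignment, table: FamilyCountTable, path: str | Path
) -> None:
    """TSV export: representative, collapsed count, number of member sequences."""
    frame = table.to_frame()
    frame["n_members"] = [len(assignment.families[r]) for r in frame["representative"]]
    frame.to_csv(path, sep="\t", index=False)


def read_family_table(path: str | Path, sample_id: str | None = None) -> FamilyCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"representative": str})
    return FamilyCountTable(
        sample_id=sample_id or Path(path).stem,
        counts=dict(zip(df["representative"], df["count"].astype(int))),
    )
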