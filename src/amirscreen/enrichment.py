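"""Per-sample frequencies, enrichment vs. the un-passaged input, hit calling.

Enrichment of a family is the ratio of its frequency after passaging to its
frequency in the input library, stabilized by a symmetric pseudocount so
that families absent from either sample (possible under bottleneck
sampling) still have finite enrichment.  A family is a hit in a replicate
when its final frequency strictly exceeds the threshold (default 1%);
recurrence counts the replicates in which it is a hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .families import FamilyCountTable

__all__ = [
    "EnrichmentRecord",
    "FrequencyTable",
    "HitCallConfig",
    "call_hits",
    "compute_frequencies",
    "enrichment_ratio",
    "pool_replicates",
    "top_n_table",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Per-sample family frequencies; sums to 1 for any non-empty sample."""

    sample_id: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq", dict(self.freq))


@dataclass(frozen=True)
class HitCallConfig:
    """Hit-calling parameters: frequency threshold, pseudocount reads, top N."""

    threshold: float = 0.01
    pseudocount: float = 0.5
    top_n: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class EnrichmentRecord:
    """One family's frequencies, enrichment, and recurrence across replicates."""

    family: str
    f_input: float
    f_p4: dict[Hashable, float]
    enrichment: dict[Hashable, float]
    pooled_f_p4: float
    recurrence: int
    is_hit: dict[Hashable, bool] = field(default_factory=dict)


def compute_frequencies(table: FamilyCountTable) -> FrequencyTable:
    """Normalize family counts to frequencies summing to 1."""
    total = table.total
    if total <= 0 or not table.counts:
        raise ValueError(f"cannot compute frequencies for empty sample {table.sample_id!r}")
    return FrequencyTable(
        sample_id=table.sample_id,
        freq={fam: c / total for fam, c in table.counts.items()},
    )


def pool_replicates(tables: Sequence[FamilyCountTable]) -> FrequencyTable:
    """Cumulative frequencies: sum counts across replicates, then normalize."""
    if not tables:
        raise ValueError("at least one table is required")
    pooled: dict[str, int] = {}
    for table in tables:
        for fam, c in table.counts.items():
            pooled[fam] = pooled.get(fam, 0) + c
    return compute_frequencies(FamilyCountTable(sample_id="pooled", counts=pooled))


def enrichment_ratio(f_p4: float, f_input: float, pseudocount_freq: float) -> float:
    """(f_p4 + eps) / (f_input + eps) with a symmetric pseudocount frequency."""
    if f_p4 < 0 or f_input < 0 or f_p4 > 1 or f_input > 1:
        raise ValueError("frequencies must lie in [0, 1]")
    if pseudocount_freq <= 0:
        raise ValueError("pseudocount_freq must be positive")
    return (f_p4 + pseudocount_freq) / (f_input + pseudocount_freq)


def call_hits(
    p4_tables: Mapping[Hashable, FamilyCountTable],
    input_table: FamilyCountTable,
    config: HitCallConfig = HitCallConfig(),
) -> list[EnrichmentRecord]:
    """Score every family observed in any sample against the input library.

    Families are harmonized across samples by exact representative sequence.
    The pseudocount frequency is ``config.pseudocount`` reads divided by the
    input sample's assigned total.  Hits use a strict ``>`` at the threshold;
    records come back sorted by pooled final frequency, descending, ties
    broken lexicographically on the representative.
    """
    if not p4_tables:
        raise ValueError("replicate set must be non-empty")
    input_freq = compute_frequencies(input_table).freq
    eps = config.pseudocount / input_table.total
    replicate_freq = {
        rep: compute_frequencies(table).freq for rep, table in p4_tables.items()
    }
    pooled = pool_replicates(list(p4_tables.values())).freq
    families = set(input_freq)
    for freq in replicate_freq.values():
        families.update(freq)
    records = []
    for fam in families:
        f_in = input_freq.get(fam, 0.0)
        f_p4 = {rep: freq.get(fam, 0.0) for rep, freq in replicate_freq.items()}
        hits = {rep: f > config.threshold for rep, f in f_p4.items()}
        records.append(
            EnrichmentRecord(
                family=fam,
                f_input=f_in,
                f_p4=f_p4,
                enrichment={
                    rep: enrichment_ratio(f, f_in, eps) for rep, f in f_p4.items()
                },
                pooled_f_p4=pooled.get(fam, 0.0),
                recurrence=sum(hits.values()),
                is_hit=hits,
            )
        )
    records.sort(key=lambda r: (-r.pooled_f_p4, r.family))
    return records


def top_n_table(
    records: Sequence[EnrichmentRecord], n: int
) -> pd.DataFrame:
    """Frequency matrix of the top-n families: input column + one per replicate.

    Rows are ordered by pooled final frequency (ties lexicographic on the
    representative).  Asking for more families than exist returns all of
    them with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not records:
        raise ValueError("no records to tabulate")
    if n > len(records):
        warnings.warn(
            f"requested top {n} families but only {len(records)} exist; returning all",
            stacklevel=2,
        )
        n = len(records)
    ordered = sorted(records, key=lambda r: (-r.pooled_f_p4, r.family))[:n]
    replicates = list(ordered[0].f_p4)
    rows = {
        r.family: [r.f_input] + [r.f_p4[rep] for rep in replicates] for r in ordered
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["input"] + [f"P4_rep{rep}" for rep in replicates]
    )


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Flat enrichment report, one row per family."""
    if not records:
        return pd.DataFrame()
    replicates = list(records[0].f_p4)
    data: dict[str, list] = {
        "family": [r.family for r in records],
        "f_input": [r.f_input for r in records],
    }
    for rep in replicates:
        data[f"f_p4_rep{rep}"] = [r.f_p4[rep] for r in records]
    for rep in replicates:
        data[f"enrichment_rep{rep}"] = [r.enrichment[rep] for r in records]
    data["pooled_f_p4"] = [r.pooled_f_p4 for r in records]
    data["recurrence"] = [r.recurrence for r in records]
    return pd.DataFrame(data)


def frequency_long_table(
    input_table: FamilyCountTable,
    p4_tables: Mapping[Hashable, FamilyCountTable],
) -> pd.DataFrame:
    """Long-format stacked-frequency table: sample, family, frequency."""
    rows = []
    for label, table in [("input", input_table)] + [
        (f"P4_rep{rep}", t) for rep, t in p4_tables.items()
    ]:
        freq = compute_frequencies(table).freq
        for fam in sorted(freq):
            rows.append((label, fam, freq[fam]))
    return pd.DataFrame(rows, columns=["sample", "family", "frequency"])


def write_enrichment_report(
    records: Sequence[EnrichmentRecord], path: str | Path
) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
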