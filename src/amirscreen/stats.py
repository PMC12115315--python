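"""Orthogonal validation statistics for screen hits.

Covers the small, exact computations used to corroborate sequencing-derived
frequencies and hit biology:

* plaque-pick concordance — exact two-sided binomial test of genotyped
  plaque counts against a sequencing frequency;
* competition-assay fitness — per-passage relative fitness ``w`` as the
  odds multiplier identified from two endpoint frequencies, and its inverse
  projection;
* differentially-expressed gene set overlap — Fisher's exact test on a 2x2
  table built from two set sizes, their intersection, and a gene universe;
* fold-change filtering, the delta-delta-Ct fold change, and dual-luciferase
  normalization.

Two-sided p-values use the minimum-likelihood ("sum of small probabilities")
convention for both the binomial and Fisher tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

__all__ = [
    "CompetitionObservation",
    "DdCtInput",
    "FitnessEstimate",
    "OverlapCounts",
    "PlaqueObservation",
    "ddct_fold_change",
    "estimate_relative_fitness",
    "fold_change_filter",
    "normalize_dual_luciferase",
    "overlap_fisher",
    "plaque_concordance_test",
    "plaque_frequency",
    "project_frequency",
]


# ---------------------------------------------------------------------------
# plaque picks


@dataclass(frozen=True)
class PlaqueObservation:
    """Genotyping of randomly picked plaques: n picked, positives per genotype."""

    n_picked: int
    k_positive: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_picked <= 0:
            raise ValueError("n_picked must be > 0")
        object.__setattr__(self, "k_positive", dict(self.k_positive))
        if any(k < 0 for k in self.k_positive.values()):
            raise ValueError("positive counts must be >= 0")
        if sum(self.k_positive.values()) > self.n_picked:
            raise ValueError("positives cannot exceed the number of picked plaques")


def plaque_frequency(obs: PlaqueObservation, genotype: str) -> float:
    """Fraction of picked plaques carrying ``genotype`` (k / n)."""
    return obs.k_positive[genotype] / obs.n_picked


def plaque_concordance_test(
    obs: PlaqueObservation, genotype: str, f_seq: float
) -> float:
    """Exact two-sided binomial p-value for plaque counts vs. a sequencing frequency.

    Minimum-likelihood convention: p = sum of P(j) over outcomes no more
    likely than the observed count under Binomial(n, f_seq).  Degenerate
    ``f_seq`` of 0 or 1 returns 0 when the observation contradicts it, else 1.
    """
    k = obs.k_positive[genotype]
    n = obs.n_picked
    if not 0.0 <= f_seq <= 1.0:
        raise ValueError("f_seq must lie in [0, 1]")
    if f_seq == 0.0:
        return 0.0 if k > 0 else 1.0
    if f_seq == 1.0:
        return 0.0 if k < n else 1.0
    return float(sps.binomtest(k, n, f_seq, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# competition assays


@dataclass(frozen=True)
class CompetitionObservation:
    """Variant frequency before (f0) and after (fT) T competition passages."""

    f0: float
    fT: float
    T: int

    def __post_init__(self) -> None:
        for name, f in (("f0", self.f0), ("fT", self.fT)):
            if not 0.0 < f < 1.0:
                raise ValueError(
                    f"{name} must lie strictly inside (0, 1); odds are undefined at the boundary"
                )
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass(frozen=True)
class FitnessEstimate:
    """Per-passage relative fitness (odds multiplier); w = 1 is neutral."""

    w: float

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("w must be > 0")


def estimate_relative_fitness(obs: CompetitionObservation) -> FitnessEstimate:
    """Identify w from two endpoints: w = [odds(fT) / odds(f0)]^(1/T)."""
    odds0 = obs.f0 / (1.0 - obs.f0)
    oddsT = obs.fT / (1.0 - obs.fT)
    return FitnessEstimate(w=float((oddsT / odds0) ** (1.0 / obs.T)))


def project_frequency(f0: float, w: float, T: int) -> float:
    """Variant frequency after T passages at per-passage odds multiplier w."""
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must lie strictly inside (0, 1)")
    if not w > 0:
        raise ValueError("w must be > 0")
    if T < 0:
        raise ValueError("T must be >= 0")
    odds = (f0 / (1.0 - f0)) * w**T
    return float(odds / (1.0 + odds))


# ---------------------------------------------------------------------------
# gene-set overlap


@dataclass(frozen=True)
class OverlapCounts:
    """Two gene-set sizes, their intersection, and the tested universe size."""

    nA: int
    nB: int
    nAB: int
    N: int

    def __post_init__(self) -> None:
        if min(self.nA, self.nB, self.nAB, self.N) < 0:
            raise ValueError("all counts must be >= 0")
        if self.nAB > min(self.nA, self.nB):
            raise ValueError("intersection cannot exceed either set size")
        if self.nA + self.nB - self.nAB > self.N:
            raise ValueError("union cannot exceed the universe size")

    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.nAB, self.nA - self.nAB],
                [self.nB - self.nAB, self.N - self.nA - self.nB + self.nAB],
            ],
            dtype=np.int64,
        )


def overlap_fisher(counts: OverlapCounts) -> tuple[float, float]:
    """Fisher's exact test of set overlap; returns (odds ratio, two-sided p).

    The odds ratio is the conditional maximum-likelihood estimate given the
    table margins (NaN for degenerate margins); the p-value follows the
    minimum-likelihood convention over the hypergeometric support.
    """
    table = counts.table()
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    try:
        odds = float(sps.contingency.odds_ratio(table, kind="conditional").statistic)
    except Exception:
        odds = float("nan")
    return odds, p


# ---------------------------------------------------------------------------
# expression-level arithmetic


def fold_change_filter(
    expr_case: Mapping[str, float],
    expr_ctrl: Mapping[str, float],
    threshold_fold: float,
) -> dict[str, str]:
    """Select differentially expressed genes by symmetric fold change.

    A gene is selected iff ``max(r, 1/r) >= threshold_fold`` where
    ``r = case/ctrl``; direction is ``"up"`` when r > 1 and ``"down"``
    otherwise.  Only genes present in both maps are considered; levels must
    be strictly positive.
    """
    if threshold_fold < 1.0:
        raise ValueError("threshold_fold must be >= 1")
    selected: dict[str, str] = {}
    for gene in sorted(set(expr_case) & set(expr_ctrl)):
        case, ctrl = expr_case[gene], expr_ctrl[gene]
        if case <= 0 or ctrl <= 0:
            raise ValueError(f"expression levels must be positive (gene {gene!r})")
        r = case / ctrl
        if max(r, 1.0 / r) >= threshold_fold:
            selected[gene] = "up" if r > 1.0 else "down"
    return selected


@dataclass(frozen=True)
class DdCtInput:
    """qPCR cycle thresholds: target & reference gene, case & control samples."""

    ct_target_case: float
    ct_ref_case: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        for f in (
            self.ct_target_case,
            self.ct_ref_case,
            self.ct_target_ctrl,
            self.ct_ref_ctrl,
        ):
            if not np.isfinite(f):
                raise ValueError("Ct values must be finite")


def ddct_fold_change(inp: DdCtInput) -> float:
    """Relative expression by the delta-delta-Ct method: 2^(-ddCt)."""
    ddct = (inp.ct_target_case - inp.ct_ref_case) - (
        inp.ct_target_ctrl - inp.ct_ref_ctrl
    )
    return float(2.0 ** (-ddct))


def normalize_dual_luciferase(
    renilla_sample: float,
    firefly_sample: float,
    renilla_ctrl: float,
    firefly_ctrl: float,
) -> float:
    """Renilla/Firefly ratio of the sample, normalized to the control pair."""
    values = (renilla_sample, firefly_sample, renilla_ctrl, firefly_ctrl)
    if any(v <= 0 for v in values):
        raise ValueError("all luminescence readings must be positive")
    return (renilla_sample / firefly_sample) / (renilla_ctrl / firefly_ctrl)
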