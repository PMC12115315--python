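"""Serial-passage population dynamics with infection bottlenecks.

Each passage models one round of the screen: a multinomial infection
bottleneck of ``round(n_cells * moi)`` virions drawn from the current pool,
followed by fitness-weighted replication to a fixed output total
(``bottleneck * burst_size`` progeny).  Selection is attributed entirely to
the tumor-cell passage; the inter-passage amplification on the production
cell line is treated as fitness-neutral expansion and is therefore absorbed
into the fixed output total.

Fitness ``w`` acts once per passage, so for a two-clone pool the expected
frequency dynamics follow the odds update ``odds_T = odds_0 * (w_A/w_B)**T``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import AmiRNALibrary, GuideSequence

__all__ = [
    "PassageConfig",
    "PoolState",
    "initial_pool",
    "largest_remainder",
    "replicate_rng",
    "run_screen",
    "simulate_competition",
    "simulate_passage",
    "trajectories_to_frame",
]


def largest_remainder(weights: Sequence[float] | np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts proportionally to ``weights``.

    Largest-remainder (Hamilton) method: floors first, then hands the
    remaining units to the largest fractional parts; ties go to the lowest
    index.  The result always sums to ``total`` exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-D array")
    if total < 0:
        raise ValueError("total must be non-negative")
    s = w.sum()
    if not np.isfinite(s) or s <= 0 or (w < 0).any():
        raise ValueError("weights must be non-negative with positive sum")
    target = w / s * total
    base = np.floor(target).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        frac = target - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class PassageConfig:
    """Study-condition parameters for one serial-passage screen.

    Defaults are the screen's conditions: 5e6 cells infected at MOI 0.1
    (bottleneck 500,000 virions), 4 passages, 5 replicates, burst size 100
    progeny per infected cell.
    """

    n_cells: int = 5_000_000
    moi: float = 0.1
    n_passages: int = 4
    n_replicates: int = 5
    burst_size: int = 100
    mode: str = "stochastic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not self.moi > 0:
            raise ValueError("moi must be > 0")
        if self.n_passages < 0:
            raise ValueError("n_passages must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.burst_size < 1:
            raise ValueError("burst_size must be >= 1")
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError("mode must be 'stochastic' or 'deterministic'")
        if self.bottleneck < 1:
            raise ValueError("bottleneck round(n_cells * moi) must be >= 1")

    @property
    def bottleneck(self) -> int:
        """Number of virions sampled into each passage: round(n_cells * moi)."""
        return int(round(self.n_cells * self.moi))

    @property
    def output_total(self) -> int:
        """Fixed progeny total per passage: bottleneck * burst_size."""
        return self.bottleneck * self.burst_size


@dataclass(frozen=True)
class PoolState:
    """Per-passage clone abundance vector; passage 0 is the un-passaged input."""

    passage_index: int
    clone_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.passage_index < 0:
            raise ValueError("passage_index must be >= 0")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size != len(self.clone_ids):
            raise ValueError("counts must be 1-D and aligned with clone_ids")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError("frequencies undefined for an empty pool")
        return self.counts / total

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.clone_ids, map(int, self.counts)))

    @classmethod
    def from_counts(
        cls, passage_index: int, counts: Mapping[str, int]
    ) -> "PoolState":
        ids = tuple(counts)
        return cls(passage_index, ids, np.array([counts[i] for i in ids]))


def initial_pool(library: AmiRNALibrary, total: int) -> PoolState:
    """Near-uniform input pool (P0) of ``total`` virions over all clones."""
    counts = largest_remainder(np.ones(library.n_clones), total)
    return PoolState(0, library.clone_ids, counts)


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate.

    Seeds are mixed with numpy's ``SeedSequence(seed, spawn_key=(replicate,))``
    so adding replicates never perturbs earlier ones.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def simulate_passage(
    pool: PoolState,
    library: AmiRNALibrary,
    config: PassageConfig,
    rng: np.random.Generator | None = None,
) -> PoolState:
    """One round of infection bottleneck plus fitness-weighted replication.

    Stochastic mode draws the bottleneck by a multinomial on current
    frequencies, then realizes progeny by a second multinomial with
    probabilities proportional to ``sampled_count * w``, to a fixed output
    total.  Deterministic mode applies ``f' = f*w / sum(f*w)`` with no
    sampling and converts back to integer counts by largest remainder.
    """
    if pool.total <= 0:
        raise ValueError("cannot passage an empty pool")
    if pool.clone_ids != library.clone_ids:
        raise ValueError("pool and library clone sets differ")
    w = library.fitness_array()
    freqs = pool.frequencies
    if config.mode == "deterministic":
        weighted = freqs * w
        if weighted.sum() <= 0:
            raise RuntimeError("population extinct: no clone with positive fitness")
        counts = largest_remainder(weighted, config.output_total)
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sampled = rng.multinomial(config.bottleneck, freqs)
        weighted = sampled * w
        total_weight = weighted.sum()
        if total_weight <= 0:
            raise RuntimeError("population extinct: no viable clone survived the bottleneck")
        counts = rng.multinomial(config.output_total, weighted / total_weight)
    return PoolState(pool.passage_index + 1, pool.clone_ids, counts)


def run_screen(
    library: AmiRNALibrary, config: PassageConfig
) -> dict[int, list[PoolState]]:
    """Run all replicates; returns replicate -> [P0, P1, ..., Pn].

    P0 is identical across replicates.  Each replicate uses an independent
    sub-seeded stream derived from ``config.seed`` (see :func:`replicate_rng`);
    deterministic mode ignores the seed entirely.
    """
    p0 = initial_pool(library, config.output_total)
    screen: dict[int, list[PoolState]] = {}
    for rep in range(1, config.n_replicates + 1):
        rng = replicate_rng(config.seed, rep)
        states = [p0]
        for _ in range(config.n_passages):
            states.append(simulate_passage(states[-1], library, config, rng=rng))
        screen[rep] = states
    return screen


def simulate_competition(
    f0: float,
    w: float,
    n_passages: int,
    *,
    mode: str = "deterministic",
    seed: int = 0,
    n_cells: int = 5_000_000,
    moi: float = 0.1,
    burst_size: int = 100,
) -> np.ndarray:
    """Two-clone competition: variant at fitness ``w`` vs neutral parent.

    Returns the variant's frequency at every passage, index 0 = start.
    Deterministic mode iterates the exact frequency map
    ``f' = f*w / (f*w + (1 - f))`` (no rounding), matching the closed-form
    odds update ``odds_T = odds_0 * w**T`` to machine precision.  Stochastic
    mode runs the integer-count bottleneck simulator.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie strictly inside (0, 1)")
    if not w > 0:
        raise ValueError("w must be > 0")
    if n_passages < 0:
        raise ValueError("n_passages must be >= 0")
    if mode == "deterministic":
        freqs = [f0]
        f = f0
        for _ in range(n_passages):
            f = f * w / (f * w + (1.0 - f))
            freqs.append(f)
        return np.array(freqs)
    config = PassageConfig(
        n_cells=n_cells,
        moi=moi,
        n_passages=n_passages,
        n_replicates=1,
        burst_size=burst_size,
        mode=mode,
        seed=seed,
    )
    clones = (GuideSequence("variant", "A" * 8), GuideSequence("parent", "C" * 8))
    lib = AmiRNALibrary(clones, fitness={"variant": float(w), "parent": 1.0})
    pool = PoolState(
        0, lib.clone_ids, largest_remainder([f0, 1.0 - f0], config.output_total)
    )
    rng = np.random.default_rng(seed)
    freqs = [pool.frequencies[0]]
    for _ in range(n_passages):
        pool = simulate_passage(pool, lib, config, rng=rng)
        freqs.append(pool.frequencies[0])
    return np.array(freqs)


def trajectories_to_frame(screen: Mapping[int, Sequence[PoolState]]) -> pd.DataFrame:
    """Long-format table of the whole screen: replicate, passage, clone_id, count."""
    rows = []
    for rep, states in screen.items():
        for state in states:
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "passage": state.passage_index,
                        "clone_id": state.clone_ids,
                        "count": state.counts,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_trajectories(
    screen: Mapping[int, Sequence[PoolState]], path: str | Path
) -> None:
    trajectories_to_frame(screen).to_csv(path, sep="\t", index=False)
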