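"""Validation statistics: exact tests, fitness estimation, qPCR arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, hypergeom

from amirscreen import (
    CompetitionObservation,
    DdCtInput,
    OverlapCounts,
    PlaqueObservation,
    ddct_fold_change,
    estimate_relative_fitness,
    fold_change_filter,
    normalize_dual_luciferase,
    overlap_fisher,
    plaque_concordance_test,
    plaque_frequency,
    project_frequency,
    simulate_competition,
)


def binom_minlike_oracle(k: int, n: int, p: float) -> float:
    """Exhaustive two-sided minimum-likelihood binomial p-value."""
    pmf = binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def fisher_minlike_oracle(counts: OverlapCounts) -> float:
    """Full hypergeometric enumeration of the two-sided Fisher p-value."""
    a = counts.nAB
    lo = max(0, counts.nA + counts.nB - counts.N)
    hi = min(counts.nA, counts.nB)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, counts.N, counts.nA, counts.nB)
    p_obs = hypergeom.pmf(a, counts.N, counts.nA, counts.nB)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


class TestPlaquePicks:
    def test_reported_pick_frequencies(self):
        obs = PlaqueObservation(20, {"amiRNA-1": 4, "amiRNA-2": 1})
        assert plaque_frequency(obs, "amiRNA-1") == pytest.approx(0.20)
        assert plaque_frequency(obs, "amiRNA-2") == pytest.approx(0.05)
        assert plaque_frequency(PlaqueObservation(20, {"x": 0}), "x") == 0.0

    def test_unknown_genotype_rejected(self):
        with pytest.raises(KeyError):
            plaque_frequency(PlaqueObservation(20, {"x": 1}), "y")

    def test_modal_outcome_gives_p_of_one(self):
        obs = PlaqueObservation(20, {"g": 4})
        assert plaque_concordance_test(obs, "g", 0.20) == pytest.approx(1.0)
        # k = n*f exactly at the mode for another configuration
        assert plaque_concordance_test(
            PlaqueObservation(25, {"g": 5}), "g", 0.2
        ) == pytest.approx(1.0)

    def test_extreme_outcome_small_p(self):
        p = plaque_concordance_test(PlaqueObservation(20, {"g": 0}), "g", 0.5)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_degenerate_sequencing_frequency(self):
        assert plaque_concordance_test(PlaqueObservation(20, {"g": 3}), "g", 0.0) == 0.0
        assert plaque_concordance_test(PlaqueObservation(20, {"g": 0}), "g", 0.0) == 1.0

    def test_matches_enumeration_oracle(self):
        for n in (5, 11, 20):
            for p in (0.05, 0.2, 0.5):
                for k in range(n + 1):
                    got = plaque_concordance_test(
                        PlaqueObservation(n, {"g": k}), "g", p
                    )
                    assert got == pytest.approx(binom_minlike_oracle(k, n, p), abs=1e-12)


class TestCompetitionFitness:
    @pytest.mark.parametrize(
        "f0,fT,w_expected",
        [(0.05, 0.76, 2.785), (0.02, 0.30, 2.141), (0.03, 0.72, 3.020), (0.08, 0.79, 2.565)],
    )
    def test_estimates_from_reported_endpoints(self, f0, fT, w_expected):
        est = estimate_relative_fitness(CompetitionObservation(f0, fT, 4))
        assert est.w == pytest.approx(w_expected, abs=1e-3)

    def test_no_change_is_neutral(self):
        assert estimate_relative_fitness(CompetitionObservation(0.3, 0.3, 4)).w == 1.0

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(ValueError):
            CompetitionObservation(0.0, 0.5, 4)
        with pytest.raises(ValueError):
            CompetitionObservation(0.5, 1.0, 4)

    @pytest.mark.parametrize(
        "f0,w,T,expected,tol",
        [(0.05, 2.785, 4, 0.760, 1e-3), (0.01, 2.0, 2, 0.0388350, 1e-6)],
    )
    def test_projection_examples(self, f0, w, T, expected, tol):
        assert project_frequency(f0, w, T) == pytest.approx(expected, abs=tol)

    def test_neutral_projection_identity(self):
        for T in (0, 1, 10):
            assert project_frequency(0.37, 1.0, T) == pytest.approx(0.37)

    def test_invalid_fitness_rejected(self):
        with pytest.raises(ValueError):
            project_frequency(0.1, 0.0, 4)

    def test_estimator_projector_round_trip_to_1e12(self):
        grid = (0.01, 0.05, 0.2, 0.5, 0.8, 0.99)
        for f0 in grid:
            for fT in grid:
                for T in (1, 2, 4, 6):
                    w = estimate_relative_fitness(CompetitionObservation(f0, fT, T)).w
                    assert abs(project_frequency(f0, w, T) - fT) < 1e-12

    def test_deterministic_simulation_recovers_w_to_1e9(self):
        for w in (0.5, 1.3, 2.785, 3.02):
            traj = simulate_competition(0.05, w, 4, mode="deterministic")
            est = estimate_relative_fitness(
                CompetitionObservation(traj[0], traj[-1], 4)
            )
            assert est.w == pytest.approx(w, abs=1e-9)

    def test_stochastic_simulation_recovers_w_within_monte_carlo_error(self):
        w_true = 2.785
        n_seeds = 200
        estimates = np.empty(n_seeds)
        for s in range(n_seeds):
            traj = simulate_competition(
                0.05, w_true, 4, mode="stochastic", seed=3_000 + s, n_cells=50_000
            )
            estimates[s] = estimate_relative_fitness(
                CompetitionObservation(traj[0], traj[-1], 4)
            ).w
        se = estimates.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(estimates.mean() - w_true) <= 3 * se


class TestOverlapFisher:
    def test_reported_de_gene_overlap_is_significant(self):
        odds, p = overlap_fisher(OverlapCounts(nA=738, nB=1090, nAB=456, N=20_000))
        assert p < 1e-4
        assert odds > 1

    def test_independent_sets_not_significant(self):
        # expected overlap of 10x10 sets in a universe of 100 is exactly 1
        _, p = overlap_fisher(OverlapCounts(nA=10, nB=10, nAB=1, N=100))
        assert p == pytest.approx(1.0)

    def test_degenerate_full_table(self):
        _, p = overlap_fisher(OverlapCounts(nA=5, nB=5, nAB=5, N=5))
        assert p == pytest.approx(1.0)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            OverlapCounts(nA=10, nB=10, nAB=11, N=100)
        with pytest.raises(ValueError):
            OverlapCounts(nA=80, nB=80, nAB=10, N=100)

    def test_matches_enumeration_oracle_on_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 40))
            nA = int(rng.integers(0, N + 1))
            nB = int(rng.integers(0, N + 1))
            lo, hi = max(0, nA + nB - N), min(nA, nB)
            nAB = int(rng.integers(lo, hi + 1))
            counts = OverlapCounts(nA=nA, nB=nB, nAB=nAB, N=N)
            _, p = overlap_fisher(counts)
            assert p == pytest.approx(fisher_minlike_oracle(counts), abs=1e-12)

    def test_significance_holds_across_plausible_universes(self):
        for N in (2_000, 10_000, 20_000, 45_000):
            _, p = overlap_fisher(OverlapCounts(nA=738, nB=1090, nAB=456, N=N))
            assert p < 1e-4


class TestFoldChangeFilter:
    def test_examples(self):
        case = {"up4": 4.0, "near": 1.0, "down2": 0.5}
        ctrl = {"up4": 1.0, "near": 1.9, "down2": 1.0}
        selected = fold_change_filter(case, ctrl, 2.0)
        assert selected == {"up4": "up", "down2": "down"}

    def test_boundary_is_inclusive(self):
        assert fold_change_filter({"g": 2.0}, {"g": 1.0}, 2.0) == {"g": "up"}

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            fold_change_filter({"g": 0.0}, {"g": 1.0}, 2.0)
        with pytest.raises(ValueError):
            fold_change_filter({"g": 1.0}, {"g": 1.0}, 0.5)

    @settings(max_examples=100, derandomize=True)
    @given(
        levels=st.dictionaries(
            st.text(st.characters(min_codepoint=97, max_codepoint=122), min_size=1, max_size=5),
            st.tuples(st.floats(0.01, 100.0), st.floats(0.01, 100.0)),
            min_size=1,
            max_size=10,
        ),
        threshold=st.floats(1.0, 10.0),
    )
    def test_direction_symmetry(self, levels, threshold):
        case = {g: a for g, (a, _) in levels.items()}
        ctrl = {g: b for g, (_, b) in levels.items()}
        fwd = fold_change_filter(case, ctrl, threshold)
        rev = fold_change_filter(ctrl, case, threshold)
        assert set(fwd) == set(rev)
        flip = {"up": "down", "down": "up"}
        for gene, direction in fwd.items():
            if case[gene] != ctrl[gene]:
                assert rev[gene] == flip[direction]


class TestQpcrAndLuciferase:
    def test_ddct_examples(self):
        assert ddct_fold_change(DdCtInput(25, 20, 25, 20)) == 1.0
        assert ddct_fold_change(DdCtInput(25, 20, 26, 20)) == pytest.approx(2.0)
        assert ddct_fold_change(DdCtInput(26, 20, 25, 20)) == pytest.approx(0.5)

    def test_ddct_requires_finite_ct(self):
        with pytest.raises(ValueError):
            DdCtInput(float("nan"), 20, 25, 20)

    def test_luciferase_normalization(self):
        assert normalize_dual_luciferase(5, 5, 5, 5) == 1.0
        assert normalize_dual_luciferase(10, 100, 50, 100) == pytest.approx(0.2)
        assert normalize_dual_luciferase(30, 300, 10, 100) == pytest.approx(1.0)

    def test_luciferase_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            normalize_dual_luciferase(0, 1, 1, 1)
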