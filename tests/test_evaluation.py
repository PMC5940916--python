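"""AUC, Spearman rho, the Boyce index, permutation importance and
response curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grainsdm.grid import Grid
from grainsdm.evaluation import (auc, boyce, cbi, permutation_importance,
                                 response_curve, spearman_rho)
from grainsdm.maxent import MaxEnt


def pair_counting_auc(pres, bg):
    wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_pairs(self):
        assert auc([0.9, 0.7], [0.8, 0.6, 0.1]) == pytest.approx(5 / 6)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_p = int(rng.integers(1, 100))
            n_b = int(rng.integers(1, 100))
            # coarse scores force plenty of ties
            p = rng.integers(0, 10, n_p) / 10
            b = rng.integers(0, 10, n_b) / 10
            assert auc(p, b) == pytest.approx(pair_counting_auc(p, b), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=rng.integers(2, 40))
        b = rng.normal(size=rng.integers(2, 40))
        assert auc(p, b) + auc(b, p) == pytest.approx(1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            auc([], [0.1])
        with pytest.raises(ValueError, match="finite"):
            auc([np.nan], [0.1])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x)[0] == pytest.approx(1.0, abs=1e-12)
        assert spearman_rho(x, x[::-1])[0] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed(self):
        rho, _ = spearman_rho([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_constant_vector_flagged_nan(self):
        rho, p = spearman_rho([1, 2, 3], [5, 5, 5])
        assert np.isnan(rho) and np.isnan(p)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])


def graded_map(n=20):
    """Grid whose cell values rise linearly from ~0 to ~1."""
    vals = (np.arange(n * n, dtype=float).reshape(n, n) + 0.5) / (n * n)
    return Grid(vals, cell_size=50.0)


def presences_at(grid, rows, cols):
    x, y = grid.cell_center(np.asarray(rows), np.asarray(cols))
    return np.column_stack([x, y])


class TestBoyce:
    def test_increasing_pe_ratio_attains_plus_one(self):
        g = graded_map()
        # presences concentrated quadratically toward high suitability
        reps = np.round(40 * (g.values.ravel() ** 2)).astype(int)
        rows, cols = np.unravel_index(np.arange(g.values.size), g.shape)
        pts = presences_at(g, np.repeat(rows, reps), np.repeat(cols, reps))
        curve = boyce(g, pts, mode="binned", nbins=4)
        assert curve.rho == pytest.approx(1.0, abs=1e-12)
        curve_c = boyce(g, pts, mode="continuous")
        assert curve_c.rho > 0.95

    def test_decreasing_pe_ratio_attains_minus_one(self):
        g = graded_map()
        reps = np.round(40 * ((1 - g.values.ravel()) ** 2)).astype(int)
        rows, cols = np.unravel_index(np.arange(g.values.size), g.shape)
        pts = presences_at(g, np.repeat(rows, reps), np.repeat(cols, reps))
        assert boyce(g, pts, mode="binned", nbins=4).rho == pytest.approx(-1.0, abs=1e-12)

    def test_random_presences_on_random_map_centre_on_zero(self):
        """A model no better than random has Boyce index near zero; the
        mean rho over 20 seeded draws must sit within +-0.3 of 0 (a single
        10-bin rho has sd of roughly 1/3)."""
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = Grid(rng.random((40, 40)), cell_size=50.0)
            rows = rng.integers(0, 40, 3000)
            cols = rng.integers(0, 40, 3000)
            pts = presences_at(g, rows, cols)
            rhos.append(boyce(g, pts, mode="binned", nbins=10).rho)
        assert abs(np.mean(rhos)) < 0.3

    def test_frequency_normalisations(self):
        g = graded_map()
        pts = presences_at(g, [0, 3, 7, 12, 19], [0, 3, 7, 12, 19])
        curve = boyce(g, pts, mode="binned", nbins=10)
        assert curve.P.sum() == pytest.approx(1.0, abs=1e-9)
        assert curve.E.sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_transform_invariance_with_quantile_bins(self):
        """Rank-quantile binning makes the index depend on ranks only."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = Grid(rng.random((30, 30)) + 0.01, cell_size=50.0)
            rows = rng.integers(0, 30, 400)
            cols = rng.integers(0, 30, 400)
            pts = presences_at(g, rows, cols)
            r1 = boyce(g, pts, mode="binned", nbins=8, binning="quantile").rho
            g2 = g.copy_with(values=g.values ** 3)       # strictly monotone
            r2 = boyce(g2, pts, mode="binned", nbins=8, binning="quantile").rho
            assert r1 == pytest.approx(r2, abs=1e-12)

    def test_empty_classes_excluded_from_rho(self):
        vals = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        g = Grid(vals.reshape(10, 10), cell_size=50.0)
        pts = presences_at(g, [9, 9, 0], [9, 8, 0])
        curve = boyce(g, pts, mode="binned", nbins=10)
        assert np.isnan(curve.F[curve.E == 0]).all()

    def test_all_presences_off_grid_is_error(self):
        g = graded_map()
        with pytest.raises(ValueError, match="valid cell"):
            boyce(g, np.array([[1e6, 1e6]]), mode="binned")


def two_variable_model(seed=0, n=400, informative_shift=2.5):
    rng = np.random.default_rng(seed)
    n_p = n // 4
    n_b = n - n_p
    X = pd.DataFrame({
        "signal": np.r_[rng.normal(informative_shift, 1, n_p),
                        rng.normal(0, 1, n_b)],
        "noise": rng.normal(size=n),
    })
    y = np.r_[np.ones(n_p), np.zeros(n_b)]
    return MaxEnt(quadratic=False, reg_beta=0.1).fit(X, y), X, y


class TestPermutationImportance:
    def test_single_variable_gets_everything(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"v": np.r_[rng.normal(2, 1, 40),
                                     rng.normal(0, 1, 160)]})
        y = np.r_[np.ones(40), np.zeros(160)]
        m = MaxEnt(quadratic=False).fit(X, y)
        imp = permutation_importance(m, X[y == 1], X[y == 0], seed=0)
        assert imp["v"] == pytest.approx(100.0)

    def test_sums_to_hundred(self):
        m, X, y = two_variable_model()
        imp = permutation_importance(m, X[y == 1], X[y == 0], seed=0)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)

    def test_noise_variable_stays_minor(self):
        for seed in range(10):
            m, X, y = two_variable_model(seed=seed, n=1200)
            imp = permutation_importance(m, X[y == 1], X[y == 0], seed=seed,
                                         n_repeats=3)
            assert imp["noise"] < 10.0


class TestResponseCurve:
    def test_positive_linear_coefficient_increases(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"v": np.r_[rng.normal(2, 1, 50),
                                     rng.normal(0, 1, 200)]})
        y = np.r_[np.ones(50), np.zeros(200)]
        m = MaxEnt(quadratic=False).fit(X, y)
        rc = response_curve(m, "v", n_points=50)
        assert np.all(np.diff(rc["suitability"]) > 0)

    def test_sweep_covers_training_range(self):
        m, X, y = two_variable_model()
        rc = response_curve(m, "signal", n_points=30)
        assert rc["value"].iloc[0] == pytest.approx(X["signal"].min())
        assert rc["value"].iloc[-1] == pytest.approx(X["signal"].max())

    def test_negative_quadratic_has_interior_maximum(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"v": np.r_[rng.normal(0, 0.4, 80),
                                     rng.uniform(-3, 3, 400)]})
        y = np.r_[np.ones(80), np.zeros(400)]
        m = MaxEnt(reg_beta=0.1).fit(X, y)
        assert m.lambdas_["v^2"] < 0
        rc = response_curve(m, "v", n_points=101)
        peak = rc["suitability"].idxmax()
        assert 0 < peak < 100

    def test_unknown_variable_rejected(self):
        m, _, _ = two_variable_model()
        with pytest.raises(ValueError, match="not in model"):
            response_curve(m, "bogus")
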