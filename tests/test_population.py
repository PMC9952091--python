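"""Heterogeneity statistics: quantile regression, quartiles, EMD, polar bins."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from chemowave.population import (emd_1d, normalized_emd, pinball_loss,
                                  polar_histogram, quantile_regress,
                                  top_quartile_proportion)
from chemowave.synthetic import SynthConfig, generate_tracks

TAUS = (0.2, 0.5, 0.8)


def grid_pinball_minimum(x, y, tau, a_range, b_range, step=0.01):
    """Brute-force pinball-loss minimisation over an (intercept, slope) grid."""
    best = np.inf
    for a in np.arange(*a_range, step):
        r = y - a - np.outer(np.arange(*b_range, step), x)
        losses = np.sum(r * (tau - (r < 0)), axis=1)
        best = min(best, losses.min())
    return best


FIXTURES = [
    ([0, 1, 2, 3, 4], [0, 1, 1, 4, 4]),
    ([0, 1, 2, 3], [1, 0, 3, 2]),
    ([0, 1, 2, 3, 4, 5], [0, 2, 1, 3, 5, 4]),
    ([0, 2, 3, 5], [4, 3, 2, 0]),
    ([0, 1, 2], [0, 1, 4]),
]


class TestQuantileRegression:
    def test_exact_line_recovered_at_all_quantiles(self):
        x = np.arange(10.0)
        fits = quantile_regress(x, 2 * x + 1, TAUS, n_boot=0)
        for f in fits.values():
            assert f.slope == pytest.approx(2.0, abs=1e-8)
            assert f.intercept == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("x,y", FIXTURES)
    @pytest.mark.parametrize("tau", TAUS)
    def test_matches_grid_oracle_on_small_fixtures(self, x, y, tau):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        fits = quantile_regress(x, y, (tau,), n_boot=0)
        f = fits[tau]
        lp_loss = pinball_loss(y - f.intercept - f.slope * x, tau)
        oracle = grid_pinball_minimum(x, y, tau, (-5, 5), (-3, 3))
        assert lp_loss <= oracle + 1e-9

    def test_matches_statsmodels_on_moderate_data(self):
        """Independent IRLS implementation agrees on a well-posed problem."""
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        y = 1.5 * x + rng.standard_normal(200)
        fits = quantile_regress(x, y, (0.5,), n_boot=0)
        model = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
        lp_loss = pinball_loss(y - fits[0.5].intercept - fits[0.5].slope * x, 0.5)
        sm_loss = pinball_loss(y - model.params[0] - model.params[1] * x, 0.5)
        # the LP solution can be no worse than IRLS and close in parameters
        assert lp_loss <= sm_loss + 1e-6
        assert fits[0.5].slope == pytest.approx(model.params[1], abs=0.02)

    def test_heteroscedastic_spread_orders_quantile_slopes(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 300)
            y = x * (1 + np.abs(rng.standard_normal(300)))
            fits = quantile_regress(x, y, (0.2, 0.8), n_boot=0)
            hits += fits[0.8].slope > fits[0.2].slope
        assert hits >= 19

    def test_degenerate_predictor_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            quantile_regress(np.ones(30), np.arange(30.0))

    def test_bootstrap_interval_covers_true_slope(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 150)
        y = 0.7 * x + rng.standard_normal(150)
        f = quantile_regress(x, y, (0.5,), n_boot=200, seed=0)[0.5]
        assert f.ci99[0] < 0.7 < f.ci99[1]
        assert f.p_value < 0.01
        assert f.slope_se > 0


class TestTopQuartile:
    def test_identical_vectors_give_one(self):
        v = np.arange(8.0)
        assert top_quartile_proportion(v, v) == 1.0

    def test_reversed_vectors_give_zero(self):
        assert top_quartile_proportion(np.arange(8.0), np.arange(8.0)[::-1]) == 0.0

    def test_independent_null_quarter(self):
        rng = np.random.default_rng(2)
        p = top_quartile_proportion(rng.uniform(size=10_000), rng.uniform(size=10_000))
        assert p == pytest.approx(0.25, abs=0.02)

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError):
            top_quartile_proportion(np.arange(5.0), np.arange(5.0))


def transportation_lp(xa, wa, xb, wb):
    """Exact Wasserstein-1 between weighted atom sets, via the LP."""
    cost = np.abs(xa[:, None] - xb[None, :]).ravel()
    na, nb = len(xa), len(xb)
    a_eq = []
    for i in range(na):
        row = np.zeros((na, nb))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(nb):
        row = np.zeros((na, nb))
        row[:, j] = 1
        a_eq.append(row.ravel())
    res = optimize.linprog(cost, A_eq=np.array(a_eq),
                           b_eq=np.concatenate([wa, wb]),
                           bounds=(0, None), method="highs")
    assert res.success
    return res.fun


class TestEMD:
    def test_identical_samples_zero(self):
        assert emd_1d([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == 0.0

    def test_point_masses(self):
        assert emd_1d([0.0], [1.0]) == pytest.approx(1.0)

    def test_shifted_pair(self):
        assert emd_1d([0.0, 1.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_agrees_with_transportation_lp(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            na, nb = rng.integers(1, 11, size=2)
            xa = np.round(rng.uniform(-5, 5, na), 3)
            xb = np.round(rng.uniform(-5, 5, nb), 3)
            lp = transportation_lp(xa, np.full(na, 1 / na), xb, np.full(nb, 1 / nb))
            assert emd_1d(xa, xb) == pytest.approx(lp, abs=1e-9)

    def test_matches_scipy_and_shift(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(0.5, 1, 10_000)
        assert emd_1d(a, b) == pytest.approx(0.5, abs=0.05)
        assert emd_1d(a, b) == pytest.approx(stats.wasserstein_distance(a, b),
                                             abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-20, 20), min_size=1, max_size=6),
           st.lists(st.integers(-20, 20), min_size=1, max_size=6),
           st.lists(st.integers(-20, 20), min_size=1, max_size=6))
    def test_metric_properties(self, a, b, c):
        a, b, c = map(np.asarray, (map(np.float64, (a, b, c))))
        dab, dba = emd_1d(a, b), emd_1d(b, a)
        assert dab == pytest.approx(dba, abs=1e-12)       # symmetry
        assert dab >= 0
        assert emd_1d(a, a) == 0                           # identity
        assert dab <= emd_1d(a, c) + emd_1d(c, b) + 1e-9   # triangle


class TestNormalizedEMD:
    def test_test_equal_to_a_control_gives_one(self):
        rng = np.random.default_rng(5)
        c1, c2 = rng.normal(0, 1, 400), rng.normal(0.05, 1, 400)
        assert normalized_emd(c2, [c1, c2]) == pytest.approx(1.0)

    def test_strong_shift_much_greater_than_one(self):
        rng = np.random.default_rng(6)
        c1 = rng.normal(0, 1, 500)
        c2 = rng.normal(0.05, 1, 500)
        test = rng.normal(10, 1, 500)
        assert normalized_emd(test, [c1, c2]) > 5

    def test_replicate_from_control_distribution_near_one(self):
        rng = np.random.default_rng(7)
        vals = [normalized_emd(rng.normal(0, 1, 400),
                               [rng.normal(0, 1, 400), rng.normal(0, 1, 400)])
                for _ in range(30)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.25)

    def test_identical_controls_refused(self):
        c = np.arange(10.0)
        with pytest.raises(ValueError, match="identical control"):
            normalized_emd(np.arange(10.0) + 1, [c, c.copy()])

    def test_single_control_refused(self):
        with pytest.raises(ValueError):
            normalized_emd([1.0], [[1.0, 2.0]])


def _straight_tracks(angles, length=10.0):
    angles = np.asarray(angles, float)
    n = len(angles)
    return pd.DataFrame({
        "cell_id": np.tile(np.arange(n), 2),
        "frame": np.repeat([0, 1], n),
        "x_um": np.concatenate([np.zeros(n), length * np.cos(angles)]),
        "y_um": np.concatenate([np.zeros(n), length * np.sin(angles)]),
    })


class TestPolarHistogram:
    def test_all_forward_single_bin(self):
        tracks = _straight_tracks(np.zeros(20))
        counts, _ = polar_histogram(tracks, n_bins=16)
        assert counts[8] == 20  # bin centred on the gradient direction
        assert counts.sum() == 20

    def test_isotropic_null_uniform(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            tracks = _straight_tracks(rng.uniform(-np.pi, np.pi, 2000))
            counts, _ = polar_histogram(tracks, n_bins=8)
            p = stats.chisquare(counts).pvalue
            hits += p > 0.01
        assert hits >= 0.95 * 40

    def test_advective_generator_forward_biased(self):
        cfg = SynthConfig(n_cells=200, duration=432, v_true=(0.05, 0.0),
                          rng_seed=8)
        tracks, _ = generate_tracks(cfg)
        counts, edges = polar_histogram(tracks, n_bins=8)
        centers = 0.5 * (edges[:-1] + edges[1:])
        forward = counts[np.abs(centers) < np.pi / 2].sum()
        assert forward / counts.sum() > 0.5

    def test_zero_axis_refused(self):
        with pytest.raises(ValueError):
            polar_histogram(_straight_tracks([0.0]), gradient_axis=(0, 0))
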