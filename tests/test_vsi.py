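"""Weak-form advection-diffusion inference against closed forms and oracles."""

import numpy as np
import pytest

from chemowave.synthetic import SynthConfig, generate_tracks
from chemowave.vsi import (DensityField, MotilityParams, build_density,
                           infer_motility, normalize_conditions, select_terms)

from conftest import NOISE_OFF


def gaussian_field(times, D=1.0, v=(0.0, 0.0), t0=1000.0, n=41, h=20.0,
                   center=(400.0, 400.0), sigma0_sq=None):
    """Analytic solution of the advection-diffusion equation: a Gaussian of
    initial variance sigma0_sq spreading at rate 2D and translating at v."""
    x = np.arange(n) * h
    y = np.arange(n) * h
    X, Y = np.meshgrid(x, y)
    if sigma0_sq is None:
        sigma0_sq = 2.0 * max(D, 1.0) * t0
    rho = []
    for t in times:
        s2 = sigma0_sq + 2.0 * D * t
        cx = center[0] + v[0] * t
        cy = center[1] + v[1] * t
        rho.append(np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * s2))
                   / (2 * np.pi * s2))
    return DensityField(np.stack(rho), x, y, np.asarray(times, float))


def strong_form_fit(field):
    """Independent oracle: finite-difference least squares on the PDE."""
    rho, h = field.rho, field.h
    rows_a, rows_b = [], []
    for n in range(rho.shape[0] - 1):
        dt = field.times[n + 1] - field.times[n]
        mid = 0.5 * (rho[n] + rho[n + 1])
        dot = (rho[n + 1] - rho[n]) / dt
        lap = (np.roll(mid, 1, 0) + np.roll(mid, -1, 0) + np.roll(mid, 1, 1)
               + np.roll(mid, -1, 1) - 4 * mid) / h ** 2
        gx = (np.roll(mid, -1, 1) - np.roll(mid, 1, 1)) / (2 * h)
        gy = (np.roll(mid, -1, 0) - np.roll(mid, 1, 0)) / (2 * h)
        sl = (slice(2, -2), slice(2, -2))
        rows_a.append(np.column_stack([lap[sl].ravel(), -gx[sl].ravel(),
                                       -gy[sl].ravel()]))
        rows_b.append(dot[sl].ravel())
    coef, *_ = np.linalg.lstsq(np.vstack(rows_a), np.concatenate(rows_b),
                               rcond=None)
    return coef  # (D, vx, vy)


class TestBuildDensity:
    def test_single_stationary_cell_mass_one(self):
        import pandas as pd
        frames = np.arange(12)
        tracks = pd.DataFrame({"cell_id": 0, "frame": frames,
                               "t_min": frames * 4.0,
                               "x_um": 400.0, "y_um": 400.0})
        field = build_density(tracks, (800, 800), aggregate_min=0)
        integral = field.rho[0].sum() * field.h ** 2
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_uniform_population_low_variation(self):
        cfg = SynthConfig(n_cells=1000, duration=432, rng_seed=1,
                          boundary="reflect")
        tracks, _ = generate_tracks(cfg)
        field = build_density(tracks, cfg.field_size, sigma_nodes=4.0)
        inner = field.rho[0][8:-8, 8:-8]
        assert inner.std() / inner.mean() < 0.2

    def test_too_few_frames_refused(self):
        import pandas as pd
        tracks = pd.DataFrame({"cell_id": [0, 0], "frame": [0, 1],
                               "t_min": [0.0, 4.0],
                               "x_um": [1.0, 2.0], "y_um": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 frames"):
            build_density(tracks, (800, 800))


class TestInferMotility:
    def test_diffusing_gaussian_recovers_D(self):
        field = gaussian_field(np.arange(50.0, 101.0, 10.0), D=1.0)
        fit = infer_motility(field)
        assert fit.D == pytest.approx(1.0, rel=0.05)
        assert np.hypot(*fit.v_xy) < 0.01

    def test_translating_gaussian_recovers_v(self):
        field = gaussian_field(np.arange(0.0, 201.0, 20.0), D=0.0,
                               v=(0.05, 0.0), t0=1000.0)
        fit = infer_motility(field)
        assert fit.v_par == pytest.approx(0.05, rel=0.10)
        assert abs(fit.v_perp) < 0.005

    def test_agrees_with_strong_form_oracle(self):
        field = gaussian_field(np.arange(50.0, 151.0, 10.0), D=0.8,
                               v=(0.03, -0.02))
        weak = infer_motility(field)
        d_fd, vx_fd, vy_fd = strong_form_fit(field)
        assert weak.D == pytest.approx(d_fd, rel=0.10)
        assert weak.v_xy[0] == pytest.approx(vx_fd, rel=0.10, abs=0.002)
        assert weak.v_xy[1] == pytest.approx(vy_fd, rel=0.10, abs=0.002)

    def test_refinement_reduces_error_monotonically(self):
        errs = []
        for n, h, step in ((21, 40.0, 40.0), (41, 20.0, 20.0), (81, 10.0, 10.0)):
            field = gaussian_field(np.arange(50.0, 251.0, step), D=1.0,
                                   n=n, h=h)
            errs.append(abs(infer_motility(field).D - 1.0))
        assert errs[0] > errs[1] > errs[2]

    def test_invariance_under_frame_relabeling_and_translation(self):
        field = gaussian_field(np.arange(50.0, 101.0, 10.0), D=1.0)
        base = infer_motility(field)
        shifted = DensityField(field.rho.copy(), field.x + 500.0,
                               field.y - 200.0, field.times + 77.0)
        moved = infer_motility(shifted)
        assert moved.D == pytest.approx(base.D, rel=1e-9)
        assert moved.v_par == pytest.approx(base.v_par, abs=1e-12)

    def test_uniform_density_rank_deficient(self):
        x = np.arange(21) * 20.0
        rho = np.ones((4, 21, 21))
        with pytest.raises(ValueError, match="uninformative"):
            infer_motility(DensityField(rho, x, x, np.arange(4) * 20.0))

    def test_random_walk_parameter_recovery(self):
        """D and drift recovered from simulated advective random walks."""
        cfg = SynthConfig(n_cells=2000, D_true=1.0, v_true=(0.05, 0.0),
                          speed_coupling=None, init_distribution="gaussian",
                          init_sigma=100.0, boundary="none",
                          noise_sd=dict(NOISE_OFF), rng_seed=5)
        tracks, _ = generate_tracks(cfg)
        fit = infer_motility(build_density(tracks, cfg.field_size))
        assert fit.D == pytest.approx(1.0, rel=0.20)
        assert fit.v_par == pytest.approx(0.05, rel=0.20)


class TestSelectTerms:
    def test_pure_diffusion_drops_advection(self):
        field = gaussian_field(np.arange(50.0, 101.0, 10.0), D=1.0)
        fit = select_terms(field)
        assert fit.active_terms == ("diffusion",)
        assert fit.D == pytest.approx(1.0, rel=0.05)

    def test_pure_advection_drops_diffusion(self):
        field = gaussian_field(np.arange(0.0, 201.0, 20.0), D=0.0,
                               v=(0.05, 0.0))
        fit = select_terms(field)
        assert "advection_x" in fit.active_terms
        assert "diffusion" not in fit.active_terms
        assert fit.v_par == pytest.approx(0.05, rel=0.10)

    def test_unit_tolerance_keeps_full_model(self):
        """Removal never decreases the loss of a nested fit, so a loss-ratio
        threshold of 1 eliminates nothing and reproduces the full fit."""
        field = gaussian_field(np.arange(50.0, 101.0, 10.0), D=1.0,
                               v=(0.02, 0.0))
        full = infer_motility(field)
        kept = select_terms(field, tol=1.0)
        assert kept.active_terms == full.active_terms
        assert kept.D == pytest.approx(full.D, rel=1e-9)


class TestNormalization:
    @staticmethod
    def _params(D, vx, vy):
        return MotilityParams(D=D, v_par=vx, v_perp=vy, v_xy=(vx, vy),
                              residual=0.0, condition=1.0)

    def test_control_vs_itself_is_unity(self):
        c = self._params(1.0, 0.05, 0.01)
        out = normalize_conditions(c, c)
        assert out.normalized_random_migration == pytest.approx(1.0)
        assert out.normalized_directed_motion == pytest.approx(1.0)

    def test_halved_diffusivity_only(self):
        c = self._params(1.0, 0.05, 0.01)
        d = self._params(0.5, 0.05, 0.01)
        out = normalize_conditions(d, c)
        assert out.normalized_random_migration == pytest.approx(0.5)
        assert out.normalized_directed_motion == pytest.approx(1.0)

    def test_zero_control_velocity_flagged(self):
        c = self._params(1.0, 0.0, 0.0)
        d = self._params(1.0, 0.05, 0.0)
        out = normalize_conditions(d, c)
        assert not out.directed_motion_defined
        assert np.isnan(out.normalized_directed_motion)

    def test_trametinib_like_condition_pattern(self):
        """Directed motion is hit harder than random migration when the
        advective component collapses (MEK-inhibition-like pattern)."""
        c = self._params(1.0, 0.05, 0.01)
        d = self._params(0.5, 0.005, 0.01)  # advection collapses to noise
        out = normalize_conditions(d, c)
        assert out.normalized_directed_motion < out.normalized_random_migration
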