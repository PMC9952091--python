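"""Heterogeneity statistics across cells and conditions.

Quantile regression (pinball loss, solved exactly as a linear program),
top-quartile co-occurrence proportions, one-dimensional earth mover's
distance (Wasserstein-1) with replicate-normalised variants, and polar
histograms of net displacement direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

DEFAULT_TAUS = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    ci99: tuple[float, float]
    n: int


def pinball_loss(u: np.ndarray, tau: float) -> float:
    """Mean-free pinball (check) loss sum: u * (tau - 1{u<0})."""
    u = np.asarray(u, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _qr_fit(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact pinball-loss minimiser via the standard LP formulation.

    Variables: intercept a = a+ - a-, slope b = b+ - b-, residual splits
    u+, u- >= 0 with y - a - b x = u+ - u-.
    """
    n = len(x)
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0],
                        np.full(n, tau), np.full(n, 1.0 - tau)])
    a_eq = np.zeros((n, 4 + 2 * n))
    a_eq[:, 0] = 1.0
    a_eq[:, 1] = -1.0
    a_eq[:, 2] = x
    a_eq[:, 3] = -x
    a_eq[:, 4:4 + n] = np.eye(n)
    a_eq[:, 4 + n:] = -np.eye(n)
    res = optimize.linprog(c, A_eq=a_eq, b_eq=y, method="highs",
                           bounds=[(0, None)] * (4 + 2 * n))
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    z = res.x
    return float(z[0] - z[1]), float(z[2] - z[3])  # intercept, slope


def quantile_regress(x, y, taus=DEFAULT_TAUS, n_boot: int = 1000,
                     seed: int = 0, min_n_boot: int = 20) -> dict[float, QuantileFit]:
    """Linear quantile regression of y on x at each tau.

    The point fit is the exact pinball-loss minimiser.  Standard errors and
    the 99% confidence interval come from a seeded case-resampling bootstrap
    (normal approximation on the bootstrap SE for the p-value); they are NaN
    when fewer than ``min_n_boot`` pairs are available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor (zero variance)")
    rng = np.random.default_rng(seed)
    fits: dict[float, QuantileFit] = {}
    for tau in taus:
        intercept, slope = _qr_fit(x, y, tau)
        se = p = np.nan
        ci = (np.nan, np.nan)
        if n >= min_n_boot and n_boot > 0:
            slopes = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                if np.ptp(x[idx]) == 0:
                    slopes[b] = slope
                    continue
                _, slopes[b] = _qr_fit(x[idx], y[idx], tau)
            se = float(slopes.std(ddof=1))
            if se > 0:
                p = float(2 * stats.norm.sf(abs(slope) / se))
                q = stats.norm.ppf(0.995)
                ci = (slope - q * se, slope + q * se)
            else:
                p, ci = 0.0, (slope, slope)
        fits[tau] = QuantileFit(tau, slope, intercept, se, p, ci, n)
    return fits


def top_quartile_proportion(speeds, amplitudes) -> float:
    """P(amplitude > its 75th pct | speed > its 75th pct); quartiles by
    linear interpolation of order statistics, strict inequalities."""
    s = np.asarray(speeds, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if len(s) != len(a):
        raise ValueError("paired vectors required")
    if len(s) < 8:
        raise ValueError("need at least 8 paired observations")
    fast = s > np.quantile(s, 0.75)
    if not fast.any():
        return float("nan")
    return float(np.mean(a[fast] > np.quantile(a, 0.75)))


def emd_1d(samples_a, samples_b) -> float:
    """Wasserstein-1 distance between two empirical distributions.

    Computed as the integral of |F_a - F_b| over the pooled support.
    """
    a = np.sort(np.asarray(samples_a, dtype=float))
    b = np.sort(np.asarray(samples_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sample sets must be nonempty")
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    deltas = np.diff(grid)
    cdf_a = np.searchsorted(a, grid[:-1], side="right") / len(a)
    cdf_b = np.searchsorted(b, grid[:-1], side="right") / len(b)
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def normalized_emd(test, controls) -> float:
    """EMD of ``test`` to the controls, normalised by inter-control EMD.

    numerator: mean over controls of emd_1d(test, control_i), skipping any
    control that is the test set itself (a relabelled replicate would
    otherwise contribute a spurious zero); denominator: mean over unordered
    control pairs of emd_1d(control_i, control_j).  Needs >= 2 control
    replicate sample sets; identical controls (zero denominator) are an
    error.
    """
    controls = list(controls)
    if len(controls) < 2:
        raise ValueError("need at least 2 control replicates")
    test_arr = np.asarray(test, dtype=float)
    others = [c for c in controls
              if not np.array_equal(test_arr, np.asarray(c, dtype=float))]
    if not others:  # test is one of the controls and all controls coincide
        others = controls
    num = float(np.mean([emd_1d(test, c) for c in others]))
    den = float(np.mean([emd_1d(ci, cj)
                         for ci, cj in itertools.combinations(controls, 2)]))
    if den == 0:
        raise ValueError("identical control replicates: normalised EMD undefined")
    return num / den


def polar_histogram(tracks, n_bins: int = 16,
                    gradient_axis: tuple[float, float] = (1.0, 0.0)):
    """Bin net-displacement angles (relative to the gradient axis).

    Bin 0 is centred on the gradient direction.  Zero-displacement tracks are
    skipped and counted in the log.  Returns (counts, bin_edges) where edges
    are relative angles in radians spanning [-pi - w/2, pi - w/2) + w, with
    w the bin width.
    """
    ux, uy = gradient_axis
    norm = np.hypot(ux, uy)
    if norm == 0:
        raise ValueError("gradient axis must be nonzero")
    axis_angle = np.arctan2(uy, ux)
    angles = []
    skipped = 0
    for _, sub in tracks.sort_values("frame").groupby("cell_id"):
        dx = sub["x_um"].iloc[-1] - sub["x_um"].iloc[0]
        dy = sub["y_um"].iloc[-1] - sub["y_um"].iloc[0]
        if dx == 0 and dy == 0:
            skipped += 1
            continue
        rel = np.arctan2(dy, dx) - axis_angle
        angles.append((rel + np.pi) % (2 * np.pi) - np.pi)
    if skipped:
        log.info("polar_histogram: skipped %d zero-displacement tracks", skipped)
    width = 2 * np.pi / n_bins
    edges = -np.pi - width / 2 + width * np.arange(n_bins + 1)
    wrapped = [(a + np.pi + width / 2) % (2 * np.pi) - np.pi - width / 2
               for a in angles]
    counts, _ = np.histogram(wrapped, bins=edges)
    return counts, edges
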