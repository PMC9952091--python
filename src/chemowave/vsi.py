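"""Weak-form inference of advection-diffusion motility parameters.

Cell positions are coarse-grained to a density field rho(x, t); the model

    d(rho)/dt = D * laplacian(rho) - v . grad(rho)

with constant diffusivity D (random migration) and advective velocity v
(directed motion) is fitted by least squares over weak-form residuals: for
every interior bilinear nodal test function w and every consecutive frame
pair,

    int w (rho^{n+1} - rho^n)/dt = -D int grad(w).grad(rho_mid)
                                   - v . int w grad(rho_mid)

with the diffusion term integrated by parts (no boundary fluxes arise
because the test functions vanish near the boundary).  A backward-elimination
pass can drop uninformative operators.  Drug conditions are compared to
control via the normalised random-migration and directed-motion ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate, gaussian_filter

log = logging.getLogger(__name__)

# Q1 (bilinear) nodal stencils on a uniform grid with spacing h.
# mass:      int w_i phi_j          = h^2/36 * M
# stiffness: int grad(w_i).grad(phi_j) = 1/3 * K
# advection: int w_i d(phi_j)/dx    = h/12 * C (and transposed for y)
_M = np.array([[1., 4., 1.], [4., 16., 4.], [1., 4., 1.]])
_K = np.array([[-1., -1., -1.], [-1., 8., -1.], [-1., -1., -1.]])
_C = np.array([[-1., 0., 1.], [-4., 0., 4.], [-1., 0., 1.]])


@dataclass
class DensityField:
    """Density snapshots on a uniform node grid.

    ``rho`` has shape (n_times, ny, nx) in cells/µm²; ``x``/``y`` are node
    coordinates (µm, uniform spacing h); ``times`` in minutes.
    """

    rho: np.ndarray
    x: np.ndarray
    y: np.ndarray
    times: np.ndarray

    @property
    def h(self) -> float:
        return float(self.x[1] - self.x[0])

    def validate(self) -> None:
        if self.rho.ndim != 3 or self.rho.shape[0] != len(self.times):
            raise ValueError("rho must be (n_times, ny, nx)")
        hx = np.diff(self.x)
        hy = np.diff(self.y)
        if not (np.allclose(hx, hx[0]) and np.allclose(hy, hy[0])
                and np.isclose(hx[0], hy[0])):
            raise ValueError("grid must be uniform with equal spacing in x and y")
        if np.any(self.rho < -1e-12):
            raise ValueError("densities must be nonnegative")


@dataclass
class MotilityParams:
    D: float                  # µm²/min
    v_par: float              # µm/min, along gradient axis
    v_perp: float
    v_xy: tuple[float, float]
    residual: float           # relative residual norm
    condition: float          # condition number of the design matrix
    active_terms: tuple[str, ...] = ("diffusion", "advection_x", "advection_y")
    model_inadequate: bool = False  # e.g. negative fitted D

    @property
    def directed_fraction(self) -> float:
        speed = float(np.hypot(self.v_par, self.v_perp))
        return self.v_par / speed if speed > 0 else float("nan")


@dataclass
class NormalizedMotility:
    normalized_random_migration: float
    normalized_directed_motion: float
    directed_motion_defined: bool = True


def build_density(tracks: pd.DataFrame,
                  field_size: tuple[float, float],
                  h: float = 20.0,
                  sigma_nodes: float = 3.0,
                  aggregate_min: float = 20.0) -> DensityField:
    """Coarse-grain tracked positions into a smoothed density field.

    Per frame, positions are histogrammed into h x h node cells, divided by
    h² (cells/µm²) and convolved with a Gaussian of ``sigma_nodes`` node
    spacings.  Frames are then averaged in blocks of ``aggregate_min``
    minutes to suppress detection noise in the time derivative.
    """
    frames = np.sort(tracks["frame"].unique())
    if len(frames) < 3:
        raise ValueError("need at least 3 frames to build a density field")
    t_by_frame = tracks.groupby("frame")["t_min"].first()
    nx = int(round(field_size[0] / h)) + 1
    ny = int(round(field_size[1] / h)) + 1
    x = np.arange(nx) * h
    y = np.arange(ny) * h
    xedges = np.concatenate([[x[0] - h / 2], x + h / 2])
    yedges = np.concatenate([[y[0] - h / 2], y + h / 2])
    fields = np.empty((len(frames), ny, nx))
    by_frame = dict(tuple(tracks.groupby("frame")))
    for i, f in enumerate(frames):
        sub = by_frame[f]
        hist, _, _ = np.histogram2d(sub["y_um"], sub["x_um"],
                                    bins=(yedges, xedges))
        fields[i] = gaussian_filter(hist / h ** 2, sigma_nodes, mode="constant")
    times = t_by_frame.loc[frames].to_numpy(dtype=float)
    # temporal aggregation
    if aggregate_min and len(times) > 1:
        dt_frame = float(np.median(np.diff(times)))
        block = max(1, int(round(aggregate_min / dt_frame)))
        n_blocks = len(frames) // block
        if n_blocks >= 2:
            fields = fields[:n_blocks * block].reshape(n_blocks, block, ny, nx).mean(axis=1)
            times = times[:n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return DensityField(rho=fields, x=x, y=y, times=times)


def _weak_system(density: DensityField, terms: tuple[str, ...]):
    density.validate()
    rho = density.rho
    h = density.h
    nt, ny, nx = rho.shape
    if nt < 2:
        raise ValueError("need at least 2 aggregated time intervals")
    if nx < 5 or ny < 5:
        raise ValueError("grid must be at least 5x5 for interior test functions")
    # exclude a one-element boundary band: interior nodes 2..n-3
    sl = (slice(2, ny - 2), slice(2, nx - 2))
    cols = {name: [] for name in terms}
    bvec = []
    for n in range(nt - 1):
        dt_n = density.times[n + 1] - density.times[n]
        mid = 0.5 * (rho[n] + rho[n + 1])
        dot = (rho[n + 1] - rho[n]) / dt_n
        bvec.append((h * h / 36.0) * correlate(dot, _M, mode="constant")[sl].ravel())
        if "diffusion" in terms:
            cols["diffusion"].append(
                -(1.0 / 3.0) * correlate(mid, _K, mode="constant")[sl].ravel())
        if "advection_x" in terms:
            cols["advection_x"].append(
                -(h / 12.0) * correlate(mid, _C, mode="constant")[sl].ravel())
        if "advection_y" in terms:
            cols["advection_y"].append(
                -(h / 12.0) * correlate(mid, _C.T, mode="constant")[sl].ravel())
    b = np.concatenate(bvec)
    a = np.column_stack([np.concatenate(cols[name]) for name in terms])
    return a, b


def _lstsq(a: np.ndarray, b: np.ndarray):
    coef, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    if rank < a.shape[1] or (sv[0] > 0 and sv[-1] / sv[0] < 1e-12):
        raise ValueError(
            "rank-deficient weak-form system: an operator is uninformative "
            "(e.g. spatially uniform density)")
    resid = b - a @ coef
    bnorm = float(np.linalg.norm(b))
    rel = float(np.linalg.norm(resid) / bnorm) if bnorm > 0 else 0.0
    cond = float(sv[0] / sv[-1])
    sse = float(resid @ resid)
    return coef, rel, cond, sse


def infer_motility(density: DensityField,
                   gradient_axis: tuple[float, float] = (1.0, 0.0),
                   terms: tuple[str, ...] = ("diffusion", "advection_x",
                                             "advection_y")) -> MotilityParams:
    """Fit (D, v) by ordinary least squares over the weak-form residuals."""
    a, b = _weak_system(density, terms)
    coef, rel, cond, _ = _lstsq(a, b)
    by_name = dict(zip(terms, coef))
    d = float(by_name.get("diffusion", 0.0))
    vx = float(by_name.get("advection_x", 0.0))
    vy = float(by_name.get("advection_y", 0.0))
    ux, uy = np.asarray(gradient_axis) / np.hypot(*gradient_axis)
    v_par = vx * ux + vy * uy
    v_perp = -vx * uy + vy * ux
    inadequate = "diffusion" in terms and d < 0
    if inadequate:
        log.warning("fitted diffusivity is negative (%.3g): model inadequacy", d)
    return MotilityParams(D=d, v_par=float(v_par), v_perp=float(v_perp),
                          v_xy=(vx, vy), residual=rel, condition=cond,
                          active_terms=tuple(terms),
                          model_inadequate=inadequate)


def select_terms(density: DensityField, tol: float = 1.5,
                 gradient_axis: tuple[float, float] = (1.0, 0.0),
                 candidates: tuple[str, ...] = ("diffusion", "advection_x",
                                                "advection_y")) -> MotilityParams:
    """Backward elimination over the operator library.

    Repeatedly drops the operator whose removal increases the least-squares
    loss by the smallest relative factor, while that factor stays below
    ``tol``; refits on the surviving set.  All operators eliminated means the
    dynamics reduce to none of the candidates (pure-decay inadequacy).
    """
    active = list(candidates)
    a, b = _weak_system(density, tuple(active))
    _, _, _, sse = _lstsq(a, b)
    while len(active) > 1:
        best = None
        for name in active:
            reduced = tuple(t for t in active if t != name)
            ar, br = _weak_system(density, reduced)
            try:
                _, _, _, sse_r = _lstsq(ar, br)
            except ValueError:
                continue
            ratio = sse_r / sse if sse > 0 else np.inf
            if best is None or ratio < best[1]:
                best = (name, ratio, sse_r)
        if best is None or best[1] >= tol:
            break
        active.remove(best[0])
        sse = best[2]
        log.info("eliminated term %s (loss ratio %.3f)", best[0], best[1])
    if len(active) == 1:
        # would dropping the last term too stay under tol? then nothing fits
        sse_null = float(b @ b)
        if sse > 0 and sse_null / sse < tol:
            log.warning("all operators eliminated: pure-decay inadequacy")
            return MotilityParams(D=float("nan"), v_par=float("nan"),
                                  v_perp=float("nan"), v_xy=(float("nan"),) * 2,
                                  residual=1.0, condition=float("nan"),
                                  active_terms=(), model_inadequate=True)
    return infer_motility(density, gradient_axis, tuple(active))


def normalize_conditions(drug: MotilityParams,
                         control: MotilityParams,
                         min_directed_fraction: float = 1e-6) -> NormalizedMotility:
    """Drug-vs-control normalised random migration and directed motion.

    normalized random migration  = D_drug / D_control
    normalized directed motion   = [v_par/|v|]_drug / [v_par/|v|]_control
    """
    if control.D <= 0:
        raise ValueError("control diffusivity must be positive")
    rand = drug.D / control.D
    ctrl_frac = control.directed_fraction
    if not np.isfinite(ctrl_frac) or abs(ctrl_frac) < min_directed_fraction:
        log.warning("control directed-motion fraction ~ 0; ratio undefined")
        return NormalizedMotility(rand, float("nan"), directed_motion_defined=False)
    return NormalizedMotility(rand, drug.directed_fraction / ctrl_frac)
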