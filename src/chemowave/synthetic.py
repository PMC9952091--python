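"""Ground-truthed synthetic single-cell chemotaxis data.

Generates per-cell tracks carrying the statistical structure the analysis
pipeline assumes: oscillatory ERK/Akt kinase-translocation-reporter (KTR)
signals with distinct short- and long-period components, aspect-ratio
oscillations anti-phased with the long ERK wave, nuclear polarization coupled
to the long-wave amplitude, speed bursts lagging aspect-ratio peaks, a linear
coupling between short-wave amplitude and mean migration speed, and population
motion following an advection-diffusion law.  A companion renderer turns
tracks into multi-channel 16-bit image stacks with ground-truth label masks.

All distances are in micrometres and all times in minutes; a pixel size
converts to pixels at render time only.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TRACK_COLUMNS = [
    "cell_id", "frame", "t_min", "x_um", "y_um", "nuc_x_um", "nuc_y_um",
    "erk_ktr", "akt_ktr", "aspect_ratio", "polarization",
    "orientation", "major_um", "minor_um", "area_um2",
]


@dataclass(frozen=True)
class AmplitudeDist:
    """Per-cell amplitude distribution.

    ``lognormal`` draws ``median * exp(sigma * Z)`` (right-skewed, matching
    observed single-cell amplitude distributions); ``constant`` returns the
    median for every cell.
    """

    family: str = "lognormal"
    median: float = 0.25
    sigma: float = 0.5

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, float(self.median))
        if self.family == "lognormal":
            return self.median * np.exp(self.sigma * rng.standard_normal(n))
        raise ValueError(f"unknown amplitude family {self.family!r}")


def _default_noise() -> dict:
    return {"erk": 0.05, "akt": 0.05, "aspect_ratio": 0.02, "polarization": 0.02}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic movie.

    Defaults emulate a 24 h chemotaxis movie imaged every 4 min: short
    signalling waves centred at 40 min (inside the 28-60 min band), long waves
    and aspect-ratio oscillations at 108 min (inside 92-124 min), a burst of
    speed peaking ``burst_gain`` above baseline ``burst_lag`` minutes after
    each aspect-ratio peak, and per-cell mean speed linear in the short-wave
    amplitude.
    """

    n_cells: int = 300
    duration: float = 1440.0          # min
    dt: float = 4.0                   # min
    field_size: tuple[float, float] = (800.0, 800.0)  # µm
    D_true: float = 0.5               # µm²/min, used when speed_coupling is None
    v_true: tuple[float, float] = (0.05, 0.0)         # µm/min, toward the gradient
    short_period: float = 40.0        # min
    long_period: float = 108.0        # min
    amp_short_dist: AmplitudeDist = field(
        default_factory=lambda: AmplitudeDist("lognormal", 0.25, 0.5))
    amp_long_dist: AmplitudeDist = field(
        default_factory=lambda: AmplitudeDist("lognormal", 0.30, 0.5))
    baseline_ktr: float = 0.5         # log2 C/N units
    akt_scale: float = 0.8            # Akt amplitude relative to ERK
    akt_scale_sigma: float = 0.2      # lognormal jitter of that factor
    # mean speed = intercept + slope * A_short; None disables the coupling
    # (positions then follow the pure advection-diffusion law with D_true).
    speed_coupling: Optional[tuple[float, float]] = (0.2, 1.2)
    ar_baseline: float = 1.6
    ar_coupling: float = 0.5          # AR oscillation amplitude = ar_coupling * A_long
    burst_lag: float = 20.0           # min after each AR peak
    burst_gain: float = 0.25          # fractional peak height above baseline
    burst_half_width: float = 20.0    # raised-cosine half-width, min
    polarization_coupling: float = 0.5  # polarization = coupling * A_long
    erk_lag: float = 0.0              # min; shifts ERK (only) relative to AR
    noise_sd: dict = field(default_factory=_default_noise)
    mitosis_rate: float = 0.0         # divisions per cell per minute (off by default)
    init_distribution: str = "uniform"  # "uniform" | "gaussian"
    init_sigma: float = 100.0         # µm, for gaussian initial placement
    boundary: str = "reflect"         # "reflect" | "none"
    edge_margin: float = 40.0         # µm cells stay inside the field border
    cell_area: float = 400.0          # µm², rendering geometry
    nucleus_area: float = 110.0       # µm²
    rng_seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 2 * self.long_period:
            raise ValueError(
                "duration must cover at least two long periods; "
                f"got {self.duration} < 2 x {self.long_period}")
        for name in ("D_true", "burst_gain", "burst_half_width",
                     "ar_coupling", "polarization_coupling", "cell_area",
                     "nucleus_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        if self.init_distribution not in ("uniform", "gaussian"):
            raise ValueError("init_distribution must be 'uniform' or 'gaussian'")
        if self.boundary not in ("reflect", "none"):
            raise ValueError("boundary must be 'reflect' or 'none'")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cells: pd.DataFrame          # one row per cell: amplitudes, phases, couplings
    signals: pd.DataFrame        # noise-free per-frame series + speed multiplier
    mitosis: list                # (parent_id, daughter_ids, frame)
    D_true: float
    v_true: tuple[float, float]
    config: SynthConfig


def _raised_cosine_kernel(t: np.ndarray, centers: np.ndarray, half_width: float) -> np.ndarray:
    """Sum of raised-cosine bumps (peak 1, support ±half_width) at ``centers``."""
    k = np.zeros_like(t, dtype=float)
    for c in centers:
        d = t - c
        inside = np.abs(d) <= half_width
        k[inside] += np.cos(np.pi * d[inside] / (2.0 * half_width)) ** 2
    return np.clip(k, 0.0, 1.0)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


class _CellDraw:
    """Per-cell latent parameters drawn once from the population laws."""

    __slots__ = ("a_short", "a_long", "psi", "phi", "akt_factor",
                 "mean_speed", "polarization", "burst_gain", "division_time")

    def __init__(self, cfg: SynthConfig, rng: np.random.Generator,
                 pol_median: float):
        self.a_short = float(cfg.amp_short_dist.sample(rng, 1)[0])
        self.a_long = float(cfg.amp_long_dist.sample(rng, 1)[0])
        self.psi = float(rng.uniform(0, 2 * np.pi))
        self.phi = float(rng.uniform(0, 2 * np.pi))
        self.akt_factor = float(
            cfg.akt_scale * np.exp(cfg.akt_scale_sigma * rng.standard_normal()))
        if cfg.speed_coupling is not None:
            b0, b1 = cfg.speed_coupling
            self.mean_speed = b0 + b1 * self.a_short
        else:
            self.mean_speed = math.nan
        self.polarization = cfg.polarization_coupling * self.a_long
        # Speed bursts ride on polarized cells: full gain above the population
        # median polarization, none below (see docs/methods.md).
        self.burst_gain = cfg.burst_gain if self.polarization > pol_median else 0.0
        if cfg.mitosis_rate > 0:
            self.division_time = float(rng.exponential(1.0 / cfg.mitosis_rate))
        else:
            self.division_time = math.inf


def _simulate_cell(cfg: SynthConfig, rng: np.random.Generator, draw: _CellDraw,
                   cell_id: int, frames: np.ndarray, x0: np.ndarray,
                   area: float):
    """Simulate one cell over the frame indices ``frames`` starting at x0."""
    t = frames * cfg.dt
    n = len(t)
    two_pi = 2 * np.pi
    erk_clean = (cfg.baseline_ktr
                 + draw.a_long * np.sin(two_pi * (t - cfg.erk_lag) / cfg.long_period + draw.psi)
                 + draw.a_short * np.sin(two_pi * (t - cfg.erk_lag) / cfg.short_period + draw.phi))
    akt_clean = (cfg.baseline_ktr
                 + draw.akt_factor * draw.a_long * np.sin(two_pi * t / cfg.long_period + draw.psi)
                 + draw.akt_factor * draw.a_short * np.sin(two_pi * t / cfg.short_period + draw.phi))
    ar_amp = cfg.ar_coupling * draw.a_long
    ar_clean = cfg.ar_baseline + ar_amp * np.sin(
        two_pi * t / cfg.long_period + draw.psi + np.pi)
    pol_clean = np.full(n, draw.polarization)

    noise = cfg.noise_sd
    erk = erk_clean + noise.get("erk", 0.0) * rng.standard_normal(n)
    akt = akt_clean + noise.get("akt", 0.0) * rng.standard_normal(n)
    ar = np.maximum(ar_clean + noise.get("aspect_ratio", 0.0) * rng.standard_normal(n), 1.001)
    pol = np.maximum(pol_clean + noise.get("polarization", 0.0) * rng.standard_normal(n), 0.0)

    # --- motion ---
    if cfg.speed_coupling is None:
        d_cell = cfg.D_true
    else:
        # For an isotropic 2D random walk the mean step length is
        # sqrt(pi * D * dt), so this diffusivity realises the target speed.
        d_cell = draw.mean_speed ** 2 * cfg.dt / np.pi
    sigma = math.sqrt(2.0 * d_cell * cfg.dt)
    steps = (np.asarray(cfg.v_true) * cfg.dt
             + sigma * rng.standard_normal((n - 1, 2)))

    # AR maxima (continuous times): sin(2 pi t / T + psi + pi) = 1
    t0 = ((np.pi / 2 - draw.psi - np.pi) % (2 * np.pi)) / (2 * np.pi) * cfg.long_period
    peaks = np.arange(t0, t[-1] + cfg.long_period, cfg.long_period)
    peaks = peaks[(peaks >= t[0]) & (peaks <= t[-1])]
    kern = _raised_cosine_kernel(t, peaks + cfg.burst_lag, cfg.burst_half_width)
    kbar = float(kern.mean())
    if draw.burst_gain > 0 and kbar < 1.0:
        # Mean-compensated burst multiplier: peaks at 1 + gain, averages to 1,
        # so bursts redistribute motility within a cycle without changing the
        # cell's mean speed.
        mult = 1.0 + draw.burst_gain * (kern - kbar) / (1.0 - kbar)
        mult = np.maximum(mult, 0.05)
    else:
        mult = np.ones(n)
    steps = steps * mult[:-1, None]

    if cfg.speed_coupling is not None:
        lengths = np.hypot(steps[:, 0], steps[:, 1])
        realised = lengths.mean()
        if realised > 0:
            steps *= (draw.mean_speed * cfg.dt) / realised

    pos = np.empty((n, 2))
    pos[0] = x0
    np.cumsum(steps, axis=0, out=pos[1:])
    pos[1:] += x0
    if cfg.boundary == "reflect":
        m = cfg.edge_margin
        pos[:, 0] = _reflect(pos[:, 0], m, cfg.field_size[0] - m)
        pos[:, 1] = _reflect(pos[:, 1], m, cfg.field_size[1] - m)

    # orientation: slowly wandering major-axis direction
    theta = rng.uniform(0, 2 * np.pi) + np.cumsum(
        0.08 * rng.standard_normal(n))
    minor = 2.0 * np.sqrt(area / (np.pi * ar))
    major = ar * minor
    nuc = pos + (pol * minor)[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])

    obs = pd.DataFrame({
        "cell_id": cell_id, "frame": frames, "t_min": t,
        "x_um": pos[:, 0], "y_um": pos[:, 1],
        "nuc_x_um": nuc[:, 0], "nuc_y_um": nuc[:, 1],
        "erk_ktr": erk, "akt_ktr": akt, "aspect_ratio": ar,
        "polarization": pol, "orientation": theta,
        "major_um": major, "minor_um": minor,
        "area_um2": float(area),
    })
    clean = pd.DataFrame({
        "cell_id": cell_id, "frame": frames,
        "erk_true": erk_clean, "akt_true": akt_clean, "ar_true": ar_clean,
        "polarization_true": pol_clean, "speed_multiplier": mult,
    })
    return obs, clean


def generate_tracks(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the synthetic movie; returns (track table, ground truth).

    The track table has one row per (cell, frame) with the standard schema
    (``TRACK_COLUMNS``); cells that divide end at the division frame and two
    daughter cells (half area) appear at the next frame. Deterministic for a
    fixed ``rng_seed``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    # closed-form population median of polarization under the log-normal law
    pol_median = cfg.polarization_coupling * cfg.amp_long_dist.median
    frames_all = np.arange(cfg.n_frames)

    obs_parts, clean_parts, cell_rows, mitosis = [], [], [], []
    next_id = 0

    def init_pos() -> np.ndarray:
        w, h = cfg.field_size
        m = cfg.edge_margin if cfg.boundary == "reflect" else 0.0
        if cfg.init_distribution == "gaussian":
            p = np.array([w / 2, h / 2]) + cfg.init_sigma * rng.standard_normal(2)
            return np.clip(p, [m, m], [w - m, h - m])
        return rng.uniform([m, m], [w - m, h - m])

    def record(draw: _CellDraw, cell_id: int, parent: Optional[int]) -> None:
        cell_rows.append({
            "cell_id": cell_id, "parent_id": -1 if parent is None else parent,
            "a_short": draw.a_short, "a_long": draw.a_long,
            "psi": draw.psi, "phi": draw.phi, "akt_factor": draw.akt_factor,
            "ar_amp": cfg.ar_coupling * draw.a_long,
            "polarization_true": draw.polarization,
            "mean_speed_target": draw.mean_speed,
            "burst_gain": draw.burst_gain,
        })

    for _ in range(cfg.n_cells):
        draw = _CellDraw(cfg, rng, pol_median)
        cid = next_id
        next_id += 1
        div_frame = (cfg.n_frames if math.isinf(draw.division_time)
                     else int(draw.division_time // cfg.dt))
        if div_frame < 2 or div_frame >= cfg.n_frames - 2:
            frames = frames_all
            o, c = _simulate_cell(cfg, rng, draw, cid, frames, init_pos(), cfg.cell_area)
            obs_parts.append(o); clean_parts.append(c); record(draw, cid, None)
            continue
        # parent up to the division frame
        o, c = _simulate_cell(cfg, rng, draw, cid, frames_all[:div_frame + 1],
                              init_pos(), cfg.cell_area)
        obs_parts.append(o); clean_parts.append(c); record(draw, cid, None)
        end = o.iloc[-1]
        offset = rng.uniform(4.0, 8.0)
        ang = rng.uniform(0, 2 * np.pi)
        dids = []
        for s in (1.0, -1.0):
            d = _CellDraw(cfg, rng, pol_median)
            did = next_id
            next_id += 1
            x0 = np.array([end.x_um + s * offset * np.cos(ang),
                           end.y_um + s * offset * np.sin(ang)])
            x0 = np.clip(x0, [0, 0], list(cfg.field_size))
            od, cdn = _simulate_cell(cfg, rng, d, did,
                                     frames_all[div_frame + 1:], x0,
                                     cfg.cell_area / 2.0)
            obs_parts.append(od); clean_parts.append(cdn); record(d, did, cid)
            dids.append(did)
        mitosis.append({"parent_id": cid, "daughter_ids": tuple(dids),
                        "frame": div_frame})

    tracks = pd.concat(obs_parts, ignore_index=True)
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows),
        signals=pd.concat(clean_parts, ignore_index=True),
        mitosis=mitosis,
        D_true=cfg.D_true, v_true=tuple(cfg.v_true), config=cfg,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class IntensityModel:
    """Intensity levels (arbitrary camera units) for the rendered channels."""

    background: float = 100.0
    nuclear_marker: float = 1000.0
    ktr_nucleus: float = 300.0     # KTR cytoplasm level = ktr_nucleus * 2**ktr
    noise_sd: float = 5.0          # additive Gaussian; 0 disables
    poisson: bool = False


def render_images(tracks: pd.DataFrame, pixel_size: float = 1.0,
                  field_size: tuple[float, float] = (800.0, 800.0),
                  intensity: Optional[IntensityModel] = None,
                  rng_seed: int = 0,
                  overlap_warn_fraction: float = 0.05):
    """Render 3-channel 16-bit stacks plus ground-truth label masks.

    Returns a dict with ``nuclear``, ``akt``, ``erk`` stacks of shape
    (frames, H, W) dtype uint16 and ``nuc_labels``/``cell_labels`` stacks of
    int32 where label k is the row's ``cell_id`` + 1.  Cells are filled
    ellipses; the nucleus is a smaller ellipse offset from the cell centroid
    along the major axis by polarization x minor-axis length.  KTR channel
    intensities are set so log2(cytoplasm mean / nucleus mean) equals the
    track's true KTR value.
    """
    from skimage.draw import ellipse as draw_ellipse

    im = intensity or IntensityModel()
    rng = np.random.default_rng(rng_seed)
    w_px = int(round(field_size[0] / pixel_size))
    h_px = int(round(field_size[1] / pixel_size))
    frames = np.sort(tracks["frame"].unique()) if len(tracks) else np.array([], dtype=int)
    n_f = len(frames)
    shape = (n_f, h_px, w_px)
    # per-frame float work buffers; stacks stored compactly
    out = {name: np.empty(shape, dtype=np.uint16)
           for name in ("nuclear", "akt", "erk")}
    nuc_lab = np.zeros(shape, dtype=np.uint16)
    cell_lab = np.zeros(shape, dtype=np.uint16)
    overlap_frames = 0

    by_frame = dict(tuple(tracks.groupby("frame"))) if len(tracks) else {}
    nuc_ar = 1.3  # fixed nucleus elongation
    buf = {name: np.empty((h_px, w_px)) for name in ("nuclear", "akt", "erk")}
    for fi, fr in enumerate(frames):
        for b in buf.values():
            b.fill(im.background)
        sub = by_frame.get(fr)
        painted = 0
        for row in (sub.itertuples() if sub is not None else ()):
            # cell ellipse (row/col = y/x in pixels)
            cy, cx = row.y_um / pixel_size, row.x_um / pixel_size
            a = row.major_um / 2.0 / pixel_size
            b_rad = row.minor_um / 2.0 / pixel_size
            # r_radius=minor, c_radius=major with rotation=-theta puts the
            # major axis along the track's orientation angle in (x, y)
            rot = -row.orientation
            rr, cc = draw_ellipse(cy, cx, b_rad, a, shape=(h_px, w_px), rotation=rot)
            label = int(row.cell_id) + 1
            buf["akt"][rr, cc] = im.ktr_nucleus * 2.0 ** row.akt_ktr
            buf["erk"][rr, cc] = im.ktr_nucleus * 2.0 ** row.erk_ktr
            cell_lab[fi, rr, cc] = label
            painted += len(rr)
            # nucleus ellipse
            area_nuc = getattr(row, "area_um2", math.nan)
            nuc_area = 110.0 if not math.isfinite(area_nuc) else min(110.0, 0.4 * area_nuc)
            nb = math.sqrt(nuc_area / (np.pi * nuc_ar)) / pixel_size
            na = nuc_ar * nb
            ny, nx = row.nuc_y_um / pixel_size, row.nuc_x_um / pixel_size
            rr, cc = draw_ellipse(ny, nx, nb, na, shape=(h_px, w_px), rotation=rot)
            buf["nuclear"][rr, cc] = im.nuclear_marker
            buf["akt"][rr, cc] = im.ktr_nucleus
            buf["erk"][rr, cc] = im.ktr_nucleus
            nuc_lab[fi, rr, cc] = label
        drawn = int((cell_lab[fi] > 0).sum())
        if painted and drawn < (1.0 - overlap_warn_fraction) * painted:
            overlap_frames += 1
        for name, arr in buf.items():
            if im.poisson:
                arr = rng.poisson(np.maximum(arr, 0)).astype(np.float64)
            if im.noise_sd > 0:
                arr = arr + im.noise_sd * rng.standard_normal(arr.shape)
            np.clip(arr, 0, 65535, out=arr)
            out[name][fi] = arr.astype(np.uint16)
    if overlap_frames:
        warnings.warn(
            f"{overlap_frames} frame(s) exceed the overlap density cap; "
            "tracking ambiguity expected", stacklevel=2)
    out["nuc_labels"] = nuc_lab
    out["cell_labels"] = cell_lab
    return out


def config_to_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["amp_short_dist"] = dataclasses.asdict(cfg.amp_short_dist)
    d["amp_long_dist"] = dataclasses.asdict(cfg.amp_long_dist)
    return d


def config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    for key in ("amp_short_dist", "amp_long_dist"):
        if key in d and isinstance(d[key], dict):
            d[key] = AmplitudeDist(**d[key])
    for key in ("field_size", "v_true", "speed_coupling"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SynthConfig(**d)
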