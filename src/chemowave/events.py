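"""Aspect-ratio peak events: isolation, alignment, and speed-burst analysis.

Every aspect-ratio peak of every cell is aligned to a common time origin so
that the surrounding detrended-ERK dip, elongation, nuclear polarization and
the lagged burst of instantaneous speed can be compared across events.  The
anti-phase coupling (aspect-ratio maxima at long-ERK minima) predicts a
near-zero lag between an aspect-ratio peak and the nearest ERK local minimum
and a negative relation between the elongation increment and the ERK drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import argrelmin, find_peaks

from . import population
from .oscillation import LONG_BAND, BandSpec, bandpass, detrend
from .tracking import compute_speeds

log = logging.getLogger(__name__)

WINDOW_MIN = 60.0  # aligned window half-width and ERK-minimum search radius


@dataclass
class PeakParams:
    prominence: float = 0.1       # minimum AR peak prominence
    separation_min: float = 48.0  # minimum peak spacing, minutes
    smooth_frames: int = 3        # moving-average width before peak picking
    min_frames: int = 60          # minimum track length admitted


@dataclass
class PeakEvent:
    cell_id: int
    t_peak: float                # min
    dt_erk_min: float            # min, signed; NaN if no minimum in window
    d_erk: float                 # detrended ERK at AR peak - at preceding AR min
    d_ar: float                  # AR at peak - at preceding min
    polarization_at_peak: float
    window_t: np.ndarray         # min, relative to the peak
    window_erk: np.ndarray
    window_ar: np.ndarray
    window_speed_ratio: np.ndarray  # s(t) / cell mean speed


def detect_ar_peaks(track: pd.DataFrame, dt: float,
                    params: PeakParams | None = None) -> np.ndarray:
    """Frame indices of qualifying aspect-ratio peaks of one track."""
    p = params or PeakParams()
    sub = track.sort_values("frame")
    if len(sub) < p.min_frames:
        return np.array([], dtype=int)
    ar = uniform_filter1d(sub["aspect_ratio"].to_numpy(dtype=float),
                          size=p.smooth_frames, mode="nearest")
    distance = max(1, int(round(p.separation_min / dt)))
    peaks, _ = find_peaks(ar, prominence=p.prominence, distance=distance)
    return peaks


def _preceding_minimum(x: np.ndarray, peak: int) -> int:
    """Index of the local minimum of x preceding ``peak`` (argmin fallback)."""
    segment = x[:peak]
    if len(segment) < 2:
        return 0
    minima = argrelmin(segment)[0]
    if len(minima):
        return int(minima[-1])
    return int(np.argmin(segment))


def align_events(track: pd.DataFrame, dt: float,
                 params: PeakParams | None = None,
                 peaks: np.ndarray | None = None) -> list[PeakEvent]:
    """Build an aligned :class:`PeakEvent` for every aspect-ratio peak."""
    p = params or PeakParams()
    sub = track.sort_values("frame").reset_index(drop=True)
    if peaks is None:
        peaks = detect_ar_peaks(sub, dt, p)
    if len(peaks) == 0:
        return []
    ar = uniform_filter1d(sub["aspect_ratio"].to_numpy(dtype=float),
                          size=p.smooth_frames, mode="nearest")
    # refine alignment on the long-band aspect-ratio component, which is
    # nearly noise-free; detection itself stays on the smoothed raw series
    ar_long = bandpass(detrend(sub["aspect_ratio"].to_numpy(dtype=float), dt),
                       BandSpec(*LONG_BAND), dt)
    refine = max(1, int(round(8.0 / dt)))
    erk_det = detrend(sub["erk_ktr"].to_numpy(dtype=float), dt)
    # ERK minima are located on the long-band component: aspect-ratio
    # oscillations live in the long band, and short waves would otherwise
    # scatter spurious minima across the search window
    erk_long = bandpass(erk_det, BandSpec(*LONG_BAND), dt)
    speeds, mean_speed = compute_speeds(sub)
    # attribute forward-difference speed to its left endpoint
    speed_series = np.concatenate([speeds, [speeds[-1]]])
    ratio = speed_series / mean_speed if mean_speed > 0 else np.full_like(speed_series, np.nan)
    t = sub["t_min"].to_numpy(dtype=float)
    cid = int(sub["cell_id"].iloc[0]) if "cell_id" in sub.columns else -1
    half = int(round(WINDOW_MIN / dt))
    erk_minima = argrelmin(erk_long)[0]

    events = []
    for pk in peaks:
        lo_r = max(0, pk - refine)
        pk = int(lo_r + np.argmax(ar_long[lo_r:pk + refine + 1]))
        if len(erk_minima):
            d_idx = erk_minima - pk
            in_win = np.abs(d_idx) <= half
            if in_win.any():
                nearest = d_idx[in_win][np.argmin(np.abs(d_idx[in_win]))]
                dt_erk = float(nearest * dt)
            else:
                dt_erk = float("nan")
        else:
            dt_erk = float("nan")
        prec = _preceding_minimum(ar, pk)
        d_ar = float(ar[pk] - ar[prec])
        d_erk = float(erk_det[pk] - erk_det[prec])
        lo, hi = pk - half, pk + half + 1
        pad_lo, pad_hi = max(0, -lo), max(0, hi - len(t))
        sl = slice(max(0, lo), min(len(t), hi))

        def padded(x: np.ndarray) -> np.ndarray:
            return np.concatenate([np.full(pad_lo, np.nan), x[sl],
                                   np.full(pad_hi, np.nan)])

        events.append(PeakEvent(
            cell_id=cid, t_peak=float(t[pk]), dt_erk_min=dt_erk,
            d_erk=d_erk, d_ar=d_ar,
            polarization_at_peak=float(sub["polarization"].iloc[pk]),
            window_t=(np.arange(-half, half + 1) * dt),
            window_erk=padded(erk_det), window_ar=padded(ar),
            window_speed_ratio=padded(ratio),
        ))
    return events


def collect_events(tracks: pd.DataFrame, dt: float,
                   params: PeakParams | None = None) -> list[PeakEvent]:
    """Events across all cells of a track table."""
    out: list[PeakEvent] = []
    for _, sub in tracks.groupby("cell_id"):
        if len(sub) < (params.min_frames if params else PeakParams().min_frames):
            continue
        out.extend(align_events(sub, dt, params))
    return out


def events_table(events: list[PeakEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": e.cell_id, "t_peak": e.t_peak, "dt_erk_min": e.dt_erk_min,
        "d_erk": e.d_erk, "d_ar": e.d_ar,
        "polarization_at_peak": e.polarization_at_peak,
    } for e in events])


def stratify_by_polarization(events: list[PeakEvent],
                             q_low: float = 0.25, q_high: float = 0.75
                             ) -> dict[str, pd.DataFrame]:
    """Mean aligned traces for polarized (top) vs non-polarized (bottom) events.

    The normalized speed trace is s(t) / (cell mean speed), further divided by
    the grand mean of that ratio over non-polarized event windows, so the
    non-polarized baseline sits at 1 by construction.
    """
    if len(events) < 40:
        raise ValueError(f"need >= 40 events to stratify, got {len(events)}")
    pol = np.array([e.polarization_at_peak for e in events])
    lo_thr, hi_thr = np.quantile(pol, [q_low, q_high])
    polarized = [e for e in events if e.polarization_at_peak >= hi_thr]
    nonpolar = [e for e in events if e.polarization_at_peak <= lo_thr]
    if not polarized or not nonpolar:
        raise ValueError("empty polarization stratum")
    baseline = np.nanmean(np.stack([e.window_speed_ratio for e in nonpolar]))
    out = {}
    for name, group in (("polarized", polarized), ("non_polarized", nonpolar)):
        erk = np.nanmean(np.stack([e.window_erk for e in group]), axis=0)
        ar = np.nanmean(np.stack([e.window_ar for e in group]), axis=0)
        spd = np.nanmean(np.stack([e.window_speed_ratio for e in group]), axis=0)
        out[name] = pd.DataFrame({
            "t_rel_min": group[0].window_t, "erk": erk, "aspect_ratio": ar,
            "norm_speed": spd / baseline, "n_events": len(group),
        })
    return out


def polarization_regressions(events: list[PeakEvent],
                             cell_mean_speeds: pd.Series | dict,
                             taus=population.DEFAULT_TAUS,
                             n_boot: int = 200, seed: int = 0) -> dict:
    """Quantile regressions tying polarization to ERK drop, elongation, speed.

    Returns fits for polarization ~ d_erk, polarization ~ d_ar, and
    cell mean speed ~ polarization.
    """
    tab = events_table(events)
    speeds = pd.Series(cell_mean_speeds)
    tab = tab[np.isfinite(tab["d_erk"]) & np.isfinite(tab["d_ar"])]
    out = {
        "polarization_vs_d_erk": population.quantile_regress(
            tab["d_erk"], tab["polarization_at_peak"], taus, n_boot, seed),
        "polarization_vs_d_ar": population.quantile_regress(
            tab["d_ar"], tab["polarization_at_peak"], taus, n_boot, seed + 1),
    }
    per_cell = tab.groupby("cell_id")["polarization_at_peak"].mean()
    joined = pd.DataFrame({"pol": per_cell}).join(
        speeds.rename("speed"), how="inner").dropna()
    out["speed_vs_polarization"] = population.quantile_regress(
        joined["pol"], joined["speed"], taus, n_boot, seed + 2)
    return out
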