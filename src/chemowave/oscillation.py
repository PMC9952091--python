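"""Period-band decomposition of single-cell signalling and morphology series.

Each cell's Akt/ERK KTR and aspect-ratio series is detrended, split into
period bands with a zero-phase discrete-Fourier brick-wall filter, and
summarised by a per-cell band amplitude (sqrt(2) x RMS, which equals the peak
amplitude of a single tone).  The canonical bands are 28-60 min (short waves)
and 92-124 min (long waves, matching the period range of aspect-ratio
oscillations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: canonical period bands, minutes
SHORT_BAND = (28.0, 60.0)
LONG_BAND = (92.0, 124.0)

#: moving-average detrend window, minutes (longer than any analysed band)
TREND_WINDOW_MIN = 200.0

#: minimum track length (frames) admitted to band analysis: 60 frames at
#: 4 min = 4 h, so the long band holds at least two cycles
MIN_TRACK_FRAMES = 60


@dataclass(frozen=True)
class BandSpec:
    period_low: float   # min
    period_high: float  # min

    def validate(self, dt: float, duration: float | None = None) -> None:
        if not (2 * dt < self.period_low < self.period_high):
            raise ValueError(
                f"band ({self.period_low}, {self.period_high}) must satisfy "
                f"2*dt < period_low < period_high (dt={dt})")
        if duration is not None and self.period_high > duration / 2:
            raise ValueError(
                f"period_high {self.period_high} exceeds half the series "
                f"duration {duration}")


def detrend(series: np.ndarray, dt: float,
            window_min: float = TREND_WINDOW_MIN) -> np.ndarray:
    """Subtract a centred moving-average trend (window ``window_min``).

    Series shorter than the trend window fall back to subtracting a global
    linear fit (logged).  NaN gaps must be interpolated beforehand.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    win = int(round(window_min / dt))
    win += 1 - win % 2  # odd
    if n < win:
        log.warning("series length %d < trend window %d; subtracting linear fit", n, win)
        t = np.arange(n)
        coef = np.polyfit(t, x, 1)
        return x - np.polyval(coef, t)
    from scipy.ndimage import uniform_filter1d
    trend = uniform_filter1d(x, size=win, mode="reflect")
    out = x - trend
    return out - out.mean()


def bandpass(series: np.ndarray, band: BandSpec, dt: float) -> np.ndarray:
    """Zero-phase brick-wall filter retaining periods in [period_low, period_high]."""
    x = np.asarray(series, dtype=float)
    band.validate(dt)
    n = len(x)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=dt)
    keep = (f >= 1.0 / band.period_high) & (f <= 1.0 / band.period_low)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n)


def band_amplitude(filtered: np.ndarray) -> float:
    """sqrt(2) x RMS of a band-filtered series (= peak amplitude of a tone)."""
    x = np.asarray(filtered, dtype=float)
    if len(x) == 0:
        return 0.0
    return float(np.sqrt(2.0 * np.mean(x ** 2)))


def _prepare(series: pd.Series, max_gap: int = 2) -> np.ndarray | None:
    """Interpolate NaN gaps up to ``max_gap`` samples; None if a longer gap."""
    x = series.to_numpy(dtype=float)
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x
    # run-length check
    run, longest = 0, 0
    for bad in isnan:
        run = run + 1 if bad else 0
        longest = max(longest, run)
    if longest > max_gap or isnan[0] or isnan[-1]:
        return None
    idx = np.arange(len(x))
    x[isnan] = np.interp(idx[isnan], idx[~isnan], x[~isnan])
    return x


def band_amplitude_table(tracks: pd.DataFrame, dt: float,
                         short_band: tuple[float, float] = SHORT_BAND,
                         long_band: tuple[float, float] = LONG_BAND,
                         min_frames: int = MIN_TRACK_FRAMES,
                         max_gap: int = 2) -> pd.DataFrame:
    """Per-cell band amplitudes and mean speed.

    Returns one row per qualifying cell with columns ``akt_short``,
    ``erk_short``, ``akt_long``, ``erk_long``, ``ar_amp`` (long band of the
    aspect ratio) and ``mean_speed`` (µm/min).  Tracks shorter than
    ``min_frames`` or with gaps longer than ``max_gap`` are excluded.
    """
    sb, lb = BandSpec(*short_band), BandSpec(*long_band)
    rows = []
    for cid, sub in tracks.sort_values("frame").groupby("cell_id"):
        # reindex to the cell's uniform frame grid so missed detections
        # appear as NaN gaps
        full = np.arange(sub["frame"].min(), sub["frame"].max() + 1)
        if len(full) > len(sub):
            sub = sub.set_index("frame").reindex(full).reset_index()
            sub["t_min"] = sub["frame"] * dt
        if len(sub) < min_frames:
            continue
        sig = {}
        ok = True
        for col in ("erk_ktr", "akt_ktr", "aspect_ratio"):
            x = _prepare(sub[col], max_gap)
            if x is None:
                ok = False
                break
            sig[col] = detrend(x, dt)
        if not ok:
            log.info("cell %s excluded from band analysis (long gap)", cid)
            continue
        pos_ok = np.isfinite(sub["x_um"].to_numpy(dtype=float))
        xs = sub["x_um"].to_numpy(dtype=float)[pos_ok]
        ys = sub["y_um"].to_numpy(dtype=float)[pos_ok]
        ts = sub["t_min"].to_numpy(dtype=float)[pos_ok]
        speed = float(np.mean(np.hypot(np.diff(xs), np.diff(ys)) / np.diff(ts)))
        rows.append({
            "cell_id": cid,
            "akt_short": band_amplitude(bandpass(sig["akt_ktr"], sb, dt)),
            "erk_short": band_amplitude(bandpass(sig["erk_ktr"], sb, dt)),
            "akt_long": band_amplitude(bandpass(sig["akt_ktr"], lb, dt)),
            "erk_long": band_amplitude(bandpass(sig["erk_ktr"], lb, dt)),
            "ar_amp": band_amplitude(bandpass(sig["aspect_ratio"], lb, dt)),
            "mean_speed": speed,
        })
    return pd.DataFrame(rows)


def _fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + conf / 2)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def amplitude_sweep(tracks: pd.DataFrame, dt: float,
                    center_periods: np.ndarray,
                    half_width: float = 16.0,
                    min_cells: int = 10,
                    min_frames: int = MIN_TRACK_FRAMES) -> pd.DataFrame:
    """Correlation of per-cell band amplitude with mean speed vs band centre.

    For each centre c the band is [c - half_width, c + half_width] min.
    Returns a table with Pearson r for ERK and Akt amplitudes vs mean speed
    plus 95% Fisher-z confidence intervals.  Centres whose band violates the
    band invariants are skipped with a log entry.
    """
    results = []
    for c in np.atleast_1d(center_periods):
        band = (c - half_width, c + half_width)
        try:
            BandSpec(*band).validate(dt)
        except ValueError as exc:
            log.info("sweep centre %.1f skipped: %s", c, exc)
            continue
        table = band_amplitude_table(tracks, dt, short_band=band,
                                     long_band=LONG_BAND, min_frames=min_frames)
        if len(table) < min_cells:
            log.info("sweep centre %.1f skipped: only %d cells", c, len(table))
            continue
        n = len(table)
        r_erk = float(np.corrcoef(table["erk_short"], table["mean_speed"])[0, 1])
        r_akt = float(np.corrcoef(table["akt_short"], table["mean_speed"])[0, 1])
        lo_e, hi_e = _fisher_ci(r_erk, n)
        lo_a, hi_a = _fisher_ci(r_akt, n)
        results.append({"center_period": float(c), "n_cells": n,
                        "r_erk": r_erk, "r_erk_lo": lo_e, "r_erk_hi": hi_e,
                        "r_akt": r_akt, "r_akt_lo": lo_a, "r_akt_hi": hi_a})
    return pd.DataFrame(results)
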