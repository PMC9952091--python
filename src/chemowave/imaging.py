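"""Segmentation and per-cell quantification of multi-channel frames.

Nuclei are found by local-mean adaptive thresholding of the nuclear-marker
channel (the reporter gives a sharp intensity step at the nuclear edge);
cytoplasm is segmented by a nucleus-seeded, marker-controlled watershed on
the combined KTR channels.  Each matched (cell, nucleus) pair yields a
CellObservation: centroids, best-fit ellipse, aspect ratio, nuclear
polarization, and the Akt/ERK KTR activities as log2 cytoplasm/nucleus mean
intensity ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

OBSERVATION_COLUMNS = [
    "cell_id", "frame", "t_min", "x_um", "y_um", "nuc_x_um", "nuc_y_um",
    "major_um", "minor_um", "orientation", "aspect_ratio", "area_um2",
    "akt_ktr", "erk_ktr", "polarization", "contact",
]


def contact_labels(cells: np.ndarray) -> set[int]:
    """Labels whose region touches another labelled region.

    Morphology of touching cells is watershed-divided rather than observed,
    so downstream shape analysis can exclude them (the classic merged-mask
    scenario).
    """
    touching: set[int] = set()
    for a, b in ((cells[:, 1:], cells[:, :-1]), (cells[1:, :], cells[:-1, :])):
        m = (a != b) & (a > 0) & (b > 0)
        touching.update(np.unique(a[m]).tolist())
        touching.update(np.unique(b[m]).tolist())
    return touching


@dataclass
class SegmentationParams:
    """Adaptive-threshold and size parameters (lengths in µm)."""

    nucleus_diameter: float = 12.0   # expected, sets the threshold window
    window_factor: float = 3.0       # window = factor x nucleus diameter
    offset_fraction: float = 0.05    # of the frame's 1st-99th pct spread
    noise_floor_snr: float = 5.0     # offset never below this x robust noise SD
    min_nucleus_area: float = 30.0   # µm²
    min_cell_area: float = 100.0     # µm²

    def window_px(self, pixel_size: float) -> int:
        w = int(round(self.window_factor * self.nucleus_diameter / pixel_size))
        return w + 1 - w % 2  # odd


@dataclass
class FrameImages:
    nuclear: np.ndarray
    akt: np.ndarray
    erk: np.ndarray
    pixel_size: float  # µm/px
    t: float           # min
    frame: int = 0

    def validate(self) -> None:
        if not (self.nuclear.shape == self.akt.shape == self.erk.shape):
            raise ValueError("channel shapes differ")
        for name in ("nuclear", "akt", "erk"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} channel has negative intensities")


def _adaptive_mask(image: np.ndarray, window_px: int, offset_fraction: float,
                   noise_floor_snr: float = 5.0) -> np.ndarray:
    """Foreground = pixels a margin above the local mean.

    The margin is a fraction of the frame's 1st-99th percentile spread, but
    never below ``noise_floor_snr`` robust noise SDs: in sparse fields the
    percentile spread collapses to the background noise and would otherwise
    admit the whole background as one connected object.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [1, 99])
    sigma = 1.4826 * np.median(np.abs(img - np.median(img)))
    offset = max(offset_fraction * (hi - lo), noise_floor_snr * sigma, 1e-12)
    thresh = threshold_local(img, block_size=window_px, method="mean",
                             offset=-offset)
    return img > thresh


def segment_nuclei(nuclear: np.ndarray, pixel_size: float,
                   params: SegmentationParams | None = None) -> np.ndarray:
    """Label mask of nuclei from the nuclear-marker channel.

    Touching nuclei are split by a watershed on the distance transform,
    seeded at distance maxima at least half a nucleus diameter apart.
    """
    p = params or SegmentationParams()
    mask = _adaptive_mask(nuclear, p.window_px(pixel_size), p.offset_fraction,
                          p.noise_floor_snr)
    mask = ndimage.binary_fill_holes(mask)
    min_px = max(1, int(round(p.min_nucleus_area / pixel_size ** 2)))
    mask = remove_small_objects(mask, max_size=min_px - 1)
    dist = ndimage.distance_transform_edt(mask)
    min_sep = max(2, int(round(0.5 * p.nucleus_diameter / pixel_size)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=cc_label(mask),
                           exclude_border=False)
    markers = np.zeros_like(mask, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=mask)
    # relabel contiguously and drop any splinters below the size floor
    sizes = np.bincount(labels.ravel())
    lut = np.zeros(len(sizes), dtype=np.int32)
    keep = np.flatnonzero(sizes >= min_px)
    keep = keep[keep > 0]
    lut[keep] = np.arange(1, len(keep) + 1)
    return lut[labels]


def segment_cells(akt: np.ndarray, erk: np.ndarray, nuclei: np.ndarray,
                  pixel_size: float,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Nucleus-seeded watershed segmentation of cell bodies.

    Foreground is the adaptive threshold of the summed KTR channels;
    marker-controlled watershed runs on the inverted summed intensity with
    the nucleus labels as seeds, so each cell inherits its nucleus label.
    Foreground blobs without a seed are discarded; nuclei falling outside
    the foreground drop their cell with a logged warning.
    """
    p = params or SegmentationParams()
    combined = np.asarray(akt, dtype=float) + np.asarray(erk, dtype=float)
    # cells are much wider than nuclei: widen the averaging window
    window = p.window_px(pixel_size) * 2 + 1
    fg = _adaptive_mask(combined, window, p.offset_fraction, p.noise_floor_snr)
    fg = ndimage.binary_fill_holes(fg) | (nuclei > 0)
    cells = watershed(-combined, markers=nuclei, mask=fg)
    min_px = max(1, int(round(p.min_cell_area / pixel_size ** 2)))
    sizes = np.bincount(cells.ravel())
    small = np.flatnonzero(sizes < min_px)
    if len(small):
        lut = np.arange(len(sizes))
        lut[small] = 0
        cells = lut[cells]
    seeded = set(np.unique(nuclei)) - {0}
    kept = set(np.unique(cells)) - {0}
    for missing in sorted(seeded - kept):
        log.warning("nucleus %d outside cell foreground; cell dropped", missing)
    return cells


def quantify_ktr(channel: np.ndarray, cell_mask: np.ndarray,
                 nucleus_mask: np.ndarray) -> float:
    """log2(mean cytoplasm intensity / mean nucleus intensity).

    Cytoplasm is the cell region minus the nucleus.  Returns NaN (invalid
    observation) for an empty cytoplasm or non-positive nuclear mean.
    """
    img = np.asarray(channel, dtype=float)
    cyto = cell_mask & ~nucleus_mask
    if not cyto.any() or not nucleus_mask.any():
        return float("nan")
    nuc_mean = img[nucleus_mask].mean()
    if nuc_mean <= 0:
        return float("nan")
    return float(np.log2(img[cyto].mean() / nuc_mean))


def measure_morphology(cell_mask: np.ndarray, nucleus_mask: np.ndarray,
                       pixel_size: float) -> dict | None:
    """Best-fit ellipse of the cell region plus nuclear polarization.

    The ellipse comes from the second central moments of the (unweighted)
    cell region; aspect ratio is major/minor; polarization is the
    nucleus-to-cell centroid distance normalised to the minor axis length.
    Degenerate regions (zero minor axis) return None.
    """
    props = regionprops(cell_mask.astype(np.uint8))
    if not props:
        return None
    r = props[0]
    minor = r.axis_minor_length * pixel_size
    major = r.axis_major_length * pixel_size
    if minor <= 0:
        return None
    nprops = regionprops(nucleus_mask.astype(np.uint8))
    if not nprops:
        return None
    cy, cx = r.centroid
    ny, nx = nprops[0].centroid
    dist = np.hypot(nx - cx, ny - cy) * pixel_size
    return {
        "x_um": cx * pixel_size, "y_um": cy * pixel_size,
        "nuc_x_um": nx * pixel_size, "nuc_y_um": ny * pixel_size,
        "major_um": major, "minor_um": minor,
        "orientation": float(r.orientation),
        "aspect_ratio": major / minor,
        "area_um2": float(r.area) * pixel_size ** 2,
        "polarization": dist / minor,
    }


def process_frame(frame: FrameImages,
                  params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment and quantify one frame; one CellObservation row per cell."""
    frame.validate()
    p = params or SegmentationParams()
    nuclei = segment_nuclei(frame.nuclear, frame.pixel_size, p)
    cells = segment_cells(frame.akt, frame.erk, nuclei, frame.pixel_size, p)
    rows = []
    touching = contact_labels(cells)
    objects = ndimage.find_objects(cells)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad one pixel so offsets below stay in-bounds
        sl = tuple(slice(max(0, s.start - 1), s.stop + 1) for s in sl)
        cell_mask = cells[sl] == lab
        nuc_mask = (nuclei[sl] == lab) & cell_mask
        if not nuc_mask.any():
            continue
        morph = measure_morphology(cell_mask, nuc_mask, frame.pixel_size)
        if morph is None:
            log.info("frame %d: degenerate region %d discarded", frame.frame, lab)
            continue
        # shift bbox-local centroids back to frame coordinates
        for key, off in (("x_um", sl[1].start), ("y_um", sl[0].start),
                         ("nuc_x_um", sl[1].start), ("nuc_y_um", sl[0].start)):
            morph[key] += off * frame.pixel_size
        morph["akt_ktr"] = quantify_ktr(frame.akt[sl], cell_mask, nuc_mask)
        morph["erk_ktr"] = quantify_ktr(frame.erk[sl], cell_mask, nuc_mask)
        morph["cell_id"] = int(lab)  # provisional, re-assigned by tracking
        morph["frame"] = frame.frame
        morph["t_min"] = frame.t
        morph["contact"] = lab in touching
        rows.append(morph)
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def process_stack(nuclear: np.ndarray, akt: np.ndarray, erk: np.ndarray,
                  pixel_size: float, dt: float,
                  params: SegmentationParams | None = None) -> pd.DataFrame:
    """Run :func:`process_frame` over (frames, H, W) stacks."""
    frames = []
    for i in range(nuclear.shape[0]):
        frames.append(process_frame(
            FrameImages(nuclear[i], akt[i], erk[i], pixel_size, t=i * dt, frame=i),
            params))
    return pd.concat(frames, ignore_index=True)
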