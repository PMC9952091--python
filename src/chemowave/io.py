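"""Format round-tripping: track CSVs, TIFF stacks, YAML configs, JSON reports."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

_HEADER = [
    "# chemowave track table",
    "# units: positions um, time min, KTR log2 cytoplasm/nucleus ratio,",
    "#        aspect ratio and polarization dimensionless",
]

REQUIRED_TRACK_COLUMNS = [
    "cell_id", "frame", "t_min", "x_um", "y_um", "nuc_x_um", "nuc_y_um",
    "erk_ktr", "akt_ktr", "aspect_ratio", "polarization",
]


def write_tracks(tracks: pd.DataFrame, path) -> None:
    """Write the track table with a unit header; lossless round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(_HEADER) + "\n")
        tracks.to_csv(fh, index=False, lineterminator="\n")


def read_tracks(path, one_based_frames: bool = False,
                max_gap: int = 2) -> pd.DataFrame:
    """Read a track CSV; empty files yield an empty table with a warning.

    ``one_based_frames`` converts tables from tools that count frames from 1.
    Tracks whose frame spacing is irregular beyond the gap rules are refused
    with the offending cell id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning empty track table", stacklevel=2)
        return pd.DataFrame(columns=REQUIRED_TRACK_COLUMNS)
    missing = [c for c in REQUIRED_TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if one_based_frames:
        df["frame"] = df["frame"] - 1
    for cid, sub in df.groupby("cell_id"):
        gaps = np.diff(np.sort(sub["frame"].to_numpy()))
        if len(gaps) and (gaps.min() < 1 or gaps.max() > max_gap + 1):
            raise ValueError(
                f"{path}: cell {cid} has non-uniform frame spacing "
                f"(gap {int(gaps.max())} frames > max_gap {max_gap}, or duplicates)")
    return df


def write_stack(stack: np.ndarray, path) -> None:
    """Write a (frames, H, W) stack as a multi-page TIFF."""
    import tifffile
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack)


def read_stack(path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(data: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(data: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
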