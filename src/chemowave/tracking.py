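"""Frame-to-frame linking of cell observations into tracks.

Nuclear positions are linked by minimum-cost one-to-one assignment
(Hungarian algorithm) on a gated cost combining displacement and relative
area change; unmatched tracks enter gap closing with an inflated gate, and
track termini followed by two nearby births of roughly conserved combined
area are resolved as mitosis with the surrounding frames trimmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

_FORBIDDEN = 1e9


@dataclass
class TrackingParams:
    d_gate: float = 30.0        # µm per frame interval
    w_area: float = 1.0         # weight of |dA|/mean(A)
    max_gap: int = 2            # frames a track may go undetected
    mitosis_gate: float = 25.0  # µm, daughter search radius
    area_tol: float = 0.35      # relative tolerance on conserved area
    trim_k: int = 3             # frames trimmed before a division


def link_cost(d: float, a0: float, a1: float, gate: float, w_area: float) -> float:
    """Gated link cost: (d/gate)^2 + w_area*|dA|/mean(A); inf beyond gate."""
    if d > gate:
        return _FORBIDDEN
    abar = 0.5 * (a0 + a1)
    area_term = abs(a1 - a0) / abar if abar > 0 else 0.0
    return (d / gate) ** 2 + w_area * area_term


def link_frames(obs_a: pd.DataFrame, obs_b: pd.DataFrame,
                params: TrackingParams | None = None,
                gate: float | None = None) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment between two frames of observations.

    Positions are nuclear centroids (``nuc_x_um``/``nuc_y_um`` when present,
    else ``x_um``/``y_um``).  Returns row-index pairs (i, j) into obs_a/obs_b;
    pairs beyond the gate are never returned.
    """
    p = params or TrackingParams()
    g = p.d_gate if gate is None else gate
    if len(obs_a) == 0 or len(obs_b) == 0:
        return []
    cost = build_cost_matrix(obs_a, obs_b, g, p.w_area)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if cost[i, j] < _FORBIDDEN]


def _positions(obs: pd.DataFrame) -> np.ndarray:
    if "nuc_x_um" in obs.columns:
        return obs[["nuc_x_um", "nuc_y_um"]].to_numpy(dtype=float)
    return obs[["x_um", "y_um"]].to_numpy(dtype=float)


def _areas(obs: pd.DataFrame) -> np.ndarray:
    if "area_um2" in obs.columns:
        return obs["area_um2"].to_numpy(dtype=float)
    return np.ones(len(obs))


def build_cost_matrix(obs_a: pd.DataFrame, obs_b: pd.DataFrame,
                      gate: float, w_area: float) -> np.ndarray:
    pa, pb = _positions(obs_a), _positions(obs_b)
    aa, ab = _areas(obs_a), _areas(obs_b)
    d = np.hypot(pa[:, None, 0] - pb[None, :, 0], pa[:, None, 1] - pb[None, :, 1])
    abar = 0.5 * (aa[:, None] + ab[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        area_term = np.where(abar > 0, np.abs(aa[:, None] - ab[None, :]) / abar, 0.0)
    cost = (d / gate) ** 2 + w_area * area_term
    cost[d > gate] = _FORBIDDEN
    return cost


@dataclass
class _Active:
    track_id: int
    rows: list = field(default_factory=list)   # global row indices
    last_row: int = -1
    gap: int = 0


def track_movie(observations: pd.DataFrame,
                params: TrackingParams | None = None) -> pd.DataFrame:
    """Link per-frame observations into tracks.

    ``observations`` needs ``frame`` plus position (and ideally area)
    columns.  Returns a copy with ``track_id`` and ``ended_by`` columns
    (``mitosis`` is assigned later by :func:`resolve_mitosis`).
    """
    p = params or TrackingParams()
    obs = observations.reset_index(drop=True).copy()
    obs["track_id"] = -1
    frames = np.sort(obs["frame"].unique())
    by_frame = {f: obs.index[obs["frame"] == f] for f in frames}

    active: list[_Active] = []
    finished: list[_Active] = []
    next_id = 0
    report = {"links": 0, "gap_links": 0, "births": 0, "lost": 0}

    for f in frames:
        idx = by_frame[f]
        det = obs.loc[idx]
        matched_det: set[int] = set()
        matched_act: set[int] = set()
        if active and len(det):
            prev = obs.loc[[a.last_row for a in active]]
            gates = np.array([p.d_gate * np.sqrt(a.gap + 1) for a in active])
            pa, pb = _positions(prev), _positions(det)
            dmat = np.hypot(pa[:, None, 0] - pb[None, :, 0],
                            pa[:, None, 1] - pb[None, :, 1])
            cost = np.where(dmat <= gates[:, None],
                            (dmat / gates[:, None]) ** 2
                            + p.w_area * _area_term(prev, det), _FORBIDDEN)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= _FORBIDDEN:
                    continue
                a = active[i]
                report["gap_links" if a.gap else "links"] += 1
                row = int(idx[j])
                a.rows.append(row)
                a.last_row = row
                a.gap = 0
                matched_det.add(j)
                matched_act.add(i)
        survivors = []
        for i, a in enumerate(active):
            if i in matched_act:
                survivors.append(a)
                continue
            a.gap += 1
            if a.gap > p.max_gap:
                a.ended_by = "lost"  # type: ignore[attr-defined]
                finished.append(a)
                report["lost"] += 1
            else:
                survivors.append(a)
        active = survivors
        for j in range(len(det)):
            if j not in matched_det:
                row = int(idx[j])
                a = _Active(next_id, [row], row, 0)
                next_id += 1
                active.append(a)
                report["births"] += 1

    for a in active:
        a.ended_by = "end_of_movie"  # type: ignore[attr-defined]
        finished.append(a)

    obs["ended_by"] = ""
    for a in finished:
        obs.loc[a.rows, "track_id"] = a.track_id
        obs.loc[a.rows, "ended_by"] = getattr(a, "ended_by", "lost")
    log.info("tracking report: %s", report)
    obs.attrs["tracking_report"] = report
    return obs


def _area_term(prev: pd.DataFrame, det: pd.DataFrame) -> np.ndarray:
    aa, ab = _areas(prev), _areas(det)
    abar = 0.5 * (aa[:, None] + ab[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(abar > 0, np.abs(aa[:, None] - ab[None, :]) / abar, 0.0)


def resolve_mitosis(tracked: pd.DataFrame,
                    params: TrackingParams | None = None) -> pd.DataFrame:
    """Trim parent tracks at divisions and mark them ``ended_by='mitosis'``.

    A division is a track terminus at frame f with exactly two track births
    at frame f+1 within the mitosis gate whose combined area matches the
    parent's area within tolerance.  The parent's last ``trim_k`` frames are
    dropped (mitotic morphology/signalling is unreliable).  Three or more
    candidate daughters are ambiguous: the terminus stays 'lost' (logged).
    """
    p = params or TrackingParams()
    obs = tracked.copy()
    trimmed_rows: list[int] = []
    starts = obs.groupby("track_id")["frame"].min()
    ends = obs.groupby("track_id")["frame"].max()
    first_frame = obs["frame"].min()
    next_id = int(obs["track_id"].max()) + 1
    divisions = []
    consumed: set[int] = set()

    def row_at(tid: int, f: int):
        m = obs[(obs["track_id"] == tid) & (obs["frame"] == f)]
        return m.iloc[0] if len(m) else None

    def area_ok(parent_area, d1_area, d2_area) -> bool:
        if not np.isfinite(parent_area):
            return True
        combined = sum(a for a in (d1_area, d2_area) if np.isfinite(a))
        return combined > 0 and abs(combined - parent_area) / parent_area <= p.area_tol

    for qid, f0 in sorted(starts.items(), key=lambda kv: kv[1]):
        if f0 <= first_frame or qid in consumed:
            continue
        q0 = row_at(qid, f0)
        cand = []  # (parent_tid, mode) where mode: "split" | "terminus"
        for tid, f_end in ends.items():
            if tid == qid or tid in consumed:
                continue
            if f_end >= f0:
                # parent may have been linked through the division: needs
                # observations straddling the birth frame
                prev = row_at(tid, f0 - 1)
                here = row_at(tid, f0)
                if prev is None or here is None:
                    continue
                d = np.hypot(q0["x_um"] - prev["x_um"], q0["y_um"] - prev["y_um"])
                if d <= p.mitosis_gate and area_ok(
                        prev.get("area_um2", np.nan),
                        here.get("area_um2", np.nan),
                        q0.get("area_um2", np.nan)):
                    cand.append((int(tid), "split"))
            elif f_end == f0 - 1:
                # parent terminated right before the birth: needs a second
                # birth at the same frame (handled when reached as qid2)
                term = row_at(tid, f_end)
                d = np.hypot(q0["x_um"] - term["x_um"], q0["y_um"] - term["y_um"])
                sibs = [s for s, fs in starts.items()
                        if s != qid and fs == f0 and s not in consumed]
                for sid in sibs:
                    s0 = row_at(sid, f0)
                    ds = np.hypot(s0["x_um"] - term["x_um"], s0["y_um"] - term["y_um"])
                    if d <= p.mitosis_gate and ds <= p.mitosis_gate and area_ok(
                            term.get("area_um2", np.nan),
                            q0.get("area_um2", np.nan),
                            s0.get("area_um2", np.nan)):
                        cand.append((int(tid), f"terminus:{int(sid)}"))
        if not cand:
            continue
        if len(cand) > 2:
            log.info("birth of track %s at frame %s: %d candidates, "
                     "ambiguous -> left as lost", qid, f0, len(cand))
            continue
        tid, mode = cand[0]
        if mode == "split":
            # parent rows from the birth frame on become a new daughter track
            rows = obs.index[(obs["track_id"] == tid) & (obs["frame"] >= f0)]
            obs.loc[rows, "track_id"] = next_id
            obs.loc[rows, "ended_by"] = obs.loc[rows[-1], "ended_by"]
            daughters = (next_id, int(qid))
            next_id += 1
        else:
            daughters = (int(qid), int(mode.split(":")[1]))
            consumed.add(daughters[1])
        keep_until = f0 - 1 - p.trim_k
        rows = obs.index[(obs["track_id"] == tid) & (obs["frame"] > keep_until)]
        trimmed_rows.extend(rows.tolist())
        obs.loc[obs["track_id"] == tid, "ended_by"] = "mitosis"
        consumed.add(int(tid))
        consumed.add(int(qid))
        divisions.append({"parent_track": int(tid), "daughter_tracks": daughters,
                          "frame": int(f0) - 1})
        ends = obs.groupby("track_id")["frame"].max()
    if trimmed_rows:
        obs = obs.drop(index=trimmed_rows).reset_index(drop=True)
    obs.attrs["divisions"] = divisions
    log.info("resolved %d divisions", len(divisions))
    return obs


def compute_speeds(track: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Instantaneous speed series (µm/min, forward difference) and mean speed.

    Gaps contribute displacement / elapsed time.  Tracks with fewer than two
    observations have no defined speed.
    """
    sub = track.sort_values("frame")
    if len(sub) < 2:
        raise ValueError("track too short for speeds")
    dx = np.diff(sub["x_um"].to_numpy(dtype=float))
    dy = np.diff(sub["y_um"].to_numpy(dtype=float))
    dtv = np.diff(sub["t_min"].to_numpy(dtype=float))
    speeds = np.hypot(dx, dy) / dtv
    return speeds, float(speeds.mean())


def link_accuracy(tracked: pd.DataFrame, truth_col: str = "cell_id") -> float:
    """Fraction of consecutive frame-to-frame links joining the same true cell."""
    correct = total = 0
    for _, sub in tracked.groupby("track_id"):
        sub = sub.sort_values("frame")
        ids = sub[truth_col].to_numpy()
        frames = sub["frame"].to_numpy()
        consec = np.diff(frames) >= 1
        total += int(consec.sum())
        correct += int(((ids[1:] == ids[:-1]) & consec).sum())
    return correct / total if total else float("nan")
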