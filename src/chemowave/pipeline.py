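"""Stage functions tying the modules into the end-to-end analysis.

Each stage reads its declared upstream artifacts from the run directory and
writes its outputs there; the CLI is a thin wrapper around these functions.
Artifacts are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import events as ev
from . import io, oscillation, population, synthetic, tracking, vsi
from .config import RunConfig
from .imaging import SegmentationParams, process_stack

log = logging.getLogger(__name__)


class MissingArtifact(FileNotFoundError):
    """An upstream stage has not been run yet."""

    def __init__(self, path, stage):
        super().__init__(f"missing artifact {path}: run the '{stage}' stage first")


def _require(cfg: RunConfig, name: str, stage: str):
    p = cfg.path(name)
    if not p.exists():
        raise MissingArtifact(p, stage)
    return p


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    scfg = cfg.synth_config()
    tracks, truth = synthetic.generate_tracks(scfg)
    io.write_tracks(tracks, cfg.path("tracks.csv"))
    io.write_json({"config": synthetic.config_to_dict(scfg),
                   "D_true": truth.D_true, "v_true": list(truth.v_true),
                   "n_cells": int(truth.cells.shape[0]),
                   "mitosis_events": len(truth.mitosis)},
                  cfg.path("ground_truth.json"))
    truth.cells.to_csv(cfg.path("ground_truth_cells.csv"), index=False)
    return tracks


def stage_render(cfg: RunConfig) -> dict:
    tracks = io.read_tracks(_require(cfg, "tracks.csv", "simulate"))
    scfg = cfg.synth_config()
    r = cfg.render
    model = synthetic.IntensityModel(r.background, r.nuclear_marker,
                                     r.ktr_nucleus, r.noise_sd, r.poisson)
    stacks = synthetic.render_images(tracks, r.pixel_size, scfg.field_size,
                                     model, rng_seed=cfg.seed)
    for name in ("nuclear", "akt", "erk"):
        io.write_stack(stacks[name], cfg.path(f"{name}.tif"))
    for name in ("nuc_labels", "cell_labels"):
        io.write_stack(stacks[name].astype(np.uint16), cfg.path(f"{name}.tif"))
    return stacks


def stage_segment(cfg: RunConfig) -> pd.DataFrame:
    for name in ("nuclear", "akt", "erk"):
        _require(cfg, f"{name}.tif", "render")
    nuclear = io.read_stack(cfg.path("nuclear.tif"))
    akt = io.read_stack(cfg.path("akt.tif"))
    erk = io.read_stack(cfg.path("erk.tif"))
    scfg = cfg.synth_config()
    params = SegmentationParams(**cfg.segmentation.model_dump())
    obs = process_stack(nuclear, akt, erk, cfg.render.pixel_size, scfg.dt, params)
    obs.to_csv(cfg.path("observations.csv"), index=False)
    return obs


def stage_track(cfg: RunConfig) -> pd.DataFrame:
    """Link observations (segmented if present, else simulated ground truth)."""
    if cfg.path("observations.csv").exists():
        obs = pd.read_csv(cfg.path("observations.csv"))
    else:
        obs = io.read_tracks(_require(cfg, "tracks.csv", "simulate"),
                             cfg.one_based_frames)
    params = tracking.TrackingParams(**cfg.tracking.model_dump())
    tracked = tracking.track_movie(obs, params)
    tracked = tracking.resolve_mitosis(tracked, params)
    report = dict(tracked.attrs.get("tracking_report", {}))
    report["divisions"] = len(tracked.attrs.get("divisions", []))
    out = tracked.rename(columns={"cell_id": "detection_id"})
    out["cell_id"] = out["track_id"]
    io.write_tracks(out, cfg.path("tracked.csv"))
    io.write_json(report, cfg.path("tracking_report.json"))
    return out


def _analysis_tracks(cfg: RunConfig) -> tuple[pd.DataFrame, float]:
    if cfg.path("tracked.csv").exists():
        tracks = io.read_tracks(cfg.path("tracked.csv"))
    else:
        tracks = io.read_tracks(_require(cfg, "tracks.csv", "simulate"))
    return tracks, cfg.synth_config().dt


def stage_oscillate(cfg: RunConfig) -> pd.DataFrame:
    tracks, dt = _analysis_tracks(cfg)
    o = cfg.oscillation
    table = oscillation.band_amplitude_table(
        tracks, dt, o.short_band, o.long_band, o.min_frames, o.max_gap)
    table.to_csv(cfg.path("amplitudes.csv"), index=False)
    if o.sweep_centers:
        sweep = oscillation.amplitude_sweep(
            tracks, dt, np.asarray(o.sweep_centers), o.sweep_half_width,
            min_frames=o.min_frames)
        sweep.to_csv(cfg.path("amplitude_sweep.csv"), index=False)
    return table


def stage_stats(cfg: RunConfig) -> dict:
    path = _require(cfg, "amplitudes.csv", "oscillate")
    table = pd.read_csv(path)
    tracks, _ = _analysis_tracks(cfg)
    s = cfg.stats
    result: dict = {"n_cells": int(len(table))}
    for col in ("akt_short", "erk_short", "akt_long", "erk_long", "ar_amp"):
        if len(table) >= 20:
            fits = population.quantile_regress(
                table[col], table["mean_speed"], s.taus, s.n_boot, cfg.seed)
            result[f"quantile_fits_{col}"] = {
                str(t): dataclasses.asdict(f) for t, f in fits.items()}
        if len(table) >= 8:
            result[f"top_quartile_{col}"] = population.top_quartile_proportion(
                table["mean_speed"], table[col])
    counts, edges = population.polar_histogram(
        tracks, s.polar_bins, cfg.gradient_axis)
    result["polar_histogram"] = {"counts": counts.tolist(),
                                 "bin_edges_rad": edges.tolist()}
    io.write_json(result, cfg.path("stats.json"))
    return result


def stage_events(cfg: RunConfig) -> dict:
    tracks, dt = _analysis_tracks(cfg)
    e = cfg.events
    params = ev.PeakParams(e.prominence, e.separation_min, e.smooth_frames,
                           e.min_frames)
    all_events = ev.collect_events(tracks, dt, params)
    table = ev.events_table(all_events)
    table.to_csv(cfg.path("events.csv"), index=False)
    out: dict = {"n_events": int(len(table))}
    if len(table):
        out["median_dt_erk_min"] = float(np.nanmedian(table["dt_erk_min"]))
    if len(all_events) >= 40:
        strata = ev.stratify_by_polarization(all_events, e.q_low, e.q_high)
        for name, df in strata.items():
            df.to_csv(cfg.path(f"events_trace_{name}.csv"), index=False)
        pol = strata["polarized"]
        peak_idx = int(pol["norm_speed"].iloc[len(pol) // 2:].idxmax())
        out["burst_peak_lag_min"] = float(pol["t_rel_min"].iloc[peak_idx])
        out["burst_peak_height"] = float(pol["norm_speed"].iloc[peak_idx])
    if len(table) >= 20:
        fits = population.quantile_regress(
            table["d_erk"], table["d_ar"], cfg.stats.taus,
            min(cfg.stats.n_boot, 200), cfg.seed)
        out["d_ar_vs_d_erk"] = {str(t): dataclasses.asdict(f)
                                for t, f in fits.items()}
    io.write_json(out, cfg.path("events_stats.json"))
    return out


def stage_vsi(cfg: RunConfig) -> dict:
    tracks, _ = _analysis_tracks(cfg)
    scfg = cfg.synth_config()
    v = cfg.vsi
    density = vsi.build_density(tracks, scfg.field_size, v.h, v.sigma_nodes,
                                v.aggregate_min)
    fit = vsi.select_terms(density, v.elimination_tol, cfg.gradient_axis)
    out = dataclasses.asdict(fit)
    out["directed_fraction"] = fit.directed_fraction
    io.write_json(out, cfg.path("vsi.json"))
    return out


def stage_report(cfg: RunConfig) -> dict:
    import json
    report: dict = {"seed": cfg.seed}
    for name, stage in (("stats.json", "stats"), ("events_stats.json", "events"),
                        ("vsi.json", "vsi"), ("tracking_report.json", "track")):
        p = cfg.path(name)
        if p.exists():
            with open(p) as fh:
                report[stage] = json.load(fh)
    io.write_json(report, cfg.path("report.json"))
    lines = ["# chemowave run report", ""]
    if "stats" in report:
        lines.append(f"- cells analysed: {report['stats'].get('n_cells')}")
        for col in ("erk_short", "akt_short"):
            key = f"top_quartile_{col}"
            if key in report["stats"]:
                lines.append(f"- top-quartile proportion ({col}): "
                             f"{report['stats'][key]:.3f}")
    if "events" in report:
        e = report["events"]
        lines.append(f"- aspect-ratio peak events: {e.get('n_events')}")
        if "burst_peak_height" in e:
            lines.append(f"- polarized speed burst: x{e['burst_peak_height']:.3f} "
                         f"at +{e['burst_peak_lag_min']:.0f} min")
    if "vsi" in report:
        vj = report["vsi"]
        lines.append(f"- VSI: D = {vj['D']:.3g} um^2/min, "
                     f"v_par = {vj['v_par']:.3g} um/min "
                     f"(terms: {', '.join(vj['active_terms'])})")
    with open(cfg.path("report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return report


STAGES = {
    "simulate": stage_simulate,
    "render": stage_render,
    "segment": stage_segment,
    "track": stage_track,
    "oscillate": stage_oscillate,
    "stats": stage_stats,
    "events": stage_events,
    "vsi": stage_vsi,
    "report": stage_report,
}
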