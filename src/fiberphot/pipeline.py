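"""End-to-end session and cohort runs driven by a single config.

A run executes the stages in dependency order — simulate (or load) ->
trim/normalize -> isosbestic fit -> subtract -> band-pass -> transient
detection -> zone assignment -> maps -> zone summary -> (positional
profile, peri-event, correlations as configured) — writes every
intermediate artifact to the output directory, and records provenance
(config hash, seed, package version) so identical config + seed reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (MazeGeometry, TrackingTrace, assign_zones,
                       classify_direction, compute_velocity, linearize_arm)
from .errors import ParameterError
from .photometry import (PhotometrySession, bandpass_filter, detect_transients,
                         fit_isosbestic, motion_correct, normalize_session)
from .spatial import (build_maps, cohort_analysis, peri_event,
                      positional_profile, zone_summary)
from .synth import gen_cohort, gen_session

log = logging.getLogger("fiberphot.pipeline")

DEFAULTS = {
    "trim_s": 60.0,
    "dff_window_s": 60.0,
    "band_low_hz": 0.2,
    "band_high_hz": 6.0,
    "k_mad": 2.0,
    "mad_window_s": 60.0,
    "bin_size_cm": 0.5,
    "velocity_threshold_mm_frame": 3.75,
    "bout_gap_s": 10.0,
    "peri_pre_s": 5.0,
    "peri_post_s": 5.0,
    "maze": {"kind": "EPM"},
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**DEFAULTS, **cfg}


def config_hash(cfg: dict) -> str:
    """Stable hash of a config after filling in the defaults."""
    blob = json.dumps({**DEFAULTS, **cfg}, sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: dict) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.get("seed", 0),
            "version": __version__}


def run_session_pipeline(cfg: dict, outdir=None) -> dict:
    """Run the full single-session chain; returns the session report dict.

    Inputs come either from ``cfg['session_csv']`` / ``cfg['tracking_csv']``
    or, when absent, from the synthetic generator under ``cfg['simulate']``.
    """
    cfg = {**DEFAULTS, **cfg}
    maze = MazeGeometry(**cfg["maze"])
    seed = int(cfg.get("seed", 0))

    if "session_csv" in cfg:
        session = PhotometrySession.from_csv(cfg["session_csv"])
        track = (TrackingTrace.from_csv(cfg["tracking_csv"], rate=session.rate)
                 if "tracking_csv" in cfg else None)
    else:
        sim = cfg.get("simulate", {})
        bundle = gen_session(maze, duration=sim.get("duration_s", 300.0),
                             zone_rates=sim.get("zone_rates"), seed=seed)
        session, track = bundle["session"], bundle["track"]

    log.info("normalizing (trim %.0f s, window %.0f s)", cfg["trim_s"],
             cfg["dff_window_s"])
    dff470, dff405 = normalize_session(session, trim=cfg["trim_s"],
                                       window=cfg["dff_window_s"])
    fit = fit_isosbestic(dff405, dff470)
    global_signal = motion_correct(dff470, fit)
    filtered = bandpass_filter(global_signal, cfg["band_low_hz"],
                               cfg["band_high_hz"])
    transients = detect_transients(filtered, k_mad=cfg["k_mad"],
                                   mad_window=cfg["mad_window_s"])
    log.info("detected %d transients", len(transients))

    report = {"provenance": _provenance(cfg),
              "isosbestic": {"slope": fit.slope, "intercept": fit.intercept},
              "n_transients": len(transients),
              "transient_rate_hz": len(transients) / (len(global_signal)
                                                      / global_signal.rate)}

    artifacts = {"dff": pd.DataFrame({"time_s": global_signal.t,
                                      "global_dff_pct": global_signal.values}),
                 "transients": transients.to_frame()}

    if track is not None:
        # align tracking to the trimmed signal
        n_trim = len(track) - len(global_signal)
        track_a = TrackingTrace(x=track.x[n_trim:], y=track.y[n_trim:],
                                rate=track.rate, t0=global_signal.t[0])
        zones = assign_zones(track_a, maze)
        maps = build_maps(global_signal, track_a, bin_size=cfg["bin_size_cm"],
                          extent=(0, 0, maze.size, maze.size))
        summary = zone_summary(global_signal, zones, transients)
        report["zone_mean_signal_pct"] = summary.mean_signal_pct
        report["differential_signal_pct"] = summary.differential_signal_pct
        ts = summary.transient_stats
        report["zone_transient_frequency_hz"] = ts.frequency_hz
        report["differential_frequency_hz"] = ts.differential_hz
        report["zone_dwell_s"] = ts.dwell_s
        artifacts["zones"] = pd.DataFrame({"time_s": zones.t,
                                           "zone": zones.labels})
        artifacts["occupancy_map"] = pd.DataFrame(maps.occupancy)
        artifacts["average_map"] = pd.DataFrame(maps.average)
        if maze.kind == "EPM":
            vel = compute_velocity(track_a)
            armpos = linearize_arm(track_a, maze)
            direction = classify_direction(
                armpos, vel, cfg["velocity_threshold_mm_frame"])
            profile = positional_profile(global_signal, armpos, direction)
            report["arm_profile"] = {"beginning_0_10_cm": profile.beginning_mean,
                                     "end_25_35_cm": profile.end_mean}

    if "events_csv" in cfg:
        ev = pd.read_csv(cfg["events_csv"])
        from .behavior import EventTrain
        events = EventTrain(times=ev["time_s"].to_numpy(float),
                            label=str(ev.get("label", [""])[0]))
        pe = peri_event(global_signal, events, pre=cfg["peri_pre_s"],
                        post=cfg["peri_post_s"])
        report["peri_event"] = {"mean_contrast_pct": pe.mean_contrast,
                                "n_events": len(pe.event_times),
                                "n_dropped": pe.n_dropped}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in artifacts.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def run_cohort_pipeline(cfg: dict, outdir=None) -> dict:
    """Simulate/analyze a cohort and compute the configured correlations."""
    cfg = {**DEFAULTS, **cfg}
    cc = cfg.get("cohort", {})
    seed = int(cfg.get("seed", 0))
    subjects, truth = gen_cohort(
        n_subjects=cc.get("n_subjects", 12),
        generating_slope=cc.get("slope", -0.01),
        generating_intercept=cc.get("intercept", 0.5),
        residual_sigma=cc.get("residual_sigma", 0.05),
        simulate_sessions=cc.get("simulate_sessions", False),
        duration=cc.get("duration_s", 900.0),
        seed=seed)
    rows = []
    for s in subjects:
        row = {k: v for k, v in s.items() if k != "bundle"}
        if "bundle" in s:
            rep = _analyze_bundle(s["bundle"], cfg)
            row.update(rep)
        rows.append(row)
    xcol = ("measured_open_time_pct" if cc.get("simulate_sessions", False)
            else "open_time_pct")
    ycol = ("measured_differential_hz" if cc.get("simulate_sessions", False)
            else "true_differential_hz")
    tail = "negative" if truth.generating_slope < 0 else "positive"
    result = cohort_analysis(rows, correlations={
        "differential_vs_open_time": (xcol, ycol, tail)})
    corr = result.correlations["differential_vs_open_time"]
    report = {"provenance": _provenance(cfg),
              "n_subjects": len(result.table),
              "correlation": {"r": corr.r, "r2": corr.r2, "p": corr.p,
                              "tail": corr.tail}}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.table.to_csv(outdir / "cohort_table.csv", index=False)
        with open(outdir / "cohort_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _analyze_bundle(bundle: dict, cfg: dict) -> dict:
    """Per-subject measured metrics from a simulated session bundle."""
    session = bundle["session"]
    zones_full = bundle["zones"]
    dff470, dff405 = normalize_session(session, trim=cfg["trim_s"],
                                       window=cfg["dff_window_s"])
    gs = motion_correct(dff470, fit_isosbestic(dff405, dff470))
    filtered = bandpass_filter(gs, cfg["band_low_hz"], cfg["band_high_hz"])
    transients = detect_transients(filtered, cfg["k_mad"], cfg["mad_window_s"])
    n_trim = len(zones_full) - len(gs)
    from .behavior import ZoneLabels
    zones = ZoneLabels(labels=zones_full.labels[n_trim:], maze=zones_full.maze,
                       rate=zones_full.rate, t0=gs.t[0])
    summary = zone_summary(gs, zones, transients)
    ts = summary.transient_stats
    analyzed = sum(d for d in ts.dwell_s.values())
    return {"measured_differential_hz": ts.differential_hz,
            "measured_open_time_pct": 100.0 * ts.dwell_s.get("open", 0.0)
            / analyzed if analyzed else np.nan}


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Dispatch to the session or cohort pipeline based on the config."""
    if "cohort" in cfg:
        return run_cohort_pipeline(cfg, outdir)
    return run_session_pipeline(cfg, outdir)
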