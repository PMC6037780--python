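"""End-to-end pipeline driver used by the command line interface.

Each stage reads and writes plain files so that partial reruns and
inspection are possible; a manifest records the ordered stages, their
artifacts, the configuration hash and the seed, and changes whenever the
configuration changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .clustering import LabelThresholds, cluster_windows, label_windows
from .corrmap import behavior_map, dominant_map, voxel_dff
from .events import (
    enforce_min_duration,
    evaluate_events,
    extract_events,
    window_labels_to_series,
)
from .features import build_backbone, extract_features
from .io import RunConfig, make_event_table, write_event_table, write_roi_traces
from .labels import PATTERNS, MotorLabel
from .motor_stats import event_frequency, transition_matrix
from .preprocess import compress_lr, compute_dff, minmax_normalize
from .synthetic import SimConfig, render_volume_movie, simulate_events, render_roi_traces
from .windowing import window_stack

logger = logging.getLogger("fictivemotor")


def config_hash(run: RunConfig, sim: Optional[SimConfig], seed: int) -> str:
    payload = {
        "run": dataclasses.asdict(run),
        "sim": dataclasses.asdict(sim) if sim is not None else None,
        "seed": seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def classify_traces(traces, config: RunConfig, overrides=None):
    """Library-level pipeline: raw traces -> (events, per-frame series, extras).

    Runs preprocessing, windowing, feature extraction, Ward clustering,
    cluster labeling (auto + optional overrides) and event extraction, and
    returns the intermediate artifacts for inspection.
    """
    dff = compute_dff(traces, config.baseline_window, config.clip_value)
    norm = minmax_normalize(dff)
    norm18 = norm if traces.n_rois == 18 else None
    norm9 = compress_lr(norm) if traces.n_rois == 18 else norm
    stack = window_stack(norm9, config.window_size, config.image_side)
    backbone = build_backbone(
        config.backbone,
        seed=config.seed,
        tap_layer=config.tap_layer,
        normalization=config.normalization,
        input_side=config.image_side,
    )
    feats = extract_features(stack, backbone)
    assignment = cluster_windows(feats, config.n_clusters)
    thresholds = LabelThresholds(
        qs_intensity=config.theta_qs,
        wave_slope=config.theta_wave,
        at_fraction=config.theta_at,
        pt_fraction=config.theta_pt,
        cos_continuity=config.theta_cos,
        gap_norm=config.theta_gap,
        vote_purity=config.vote_purity,
    )
    window_labels, label_map = label_windows(
        assignment, stack.tensors, thresholds, overrides=overrides
    )
    series = window_labels_to_series(
        window_labels, stack.center_frames, norm9.n_valid_frames, config.window_size
    )
    min_frames = int(round(config.min_event_s / traces.frame_interval_s))
    series = enforce_min_duration(series, min_frames)
    events = extract_events(series, traces.frame_interval_s, norm=norm9, norm18=norm18)
    return {
        "dff": dff,
        "norm": norm,
        "norm9": norm9,
        "stack": stack,
        "features": feats,
        "assignment": assignment,
        "label_map": label_map,
        "series": series,
        "events": events,
    }


def run_demo(
    outdir,
    run_config: Optional[RunConfig] = None,
    sim_config: Optional[SimConfig] = None,
    seed: int = 0,
    movie_frames: int = 400,
) -> dict:
    """One-command synthetic demo: simulate, classify, score, map.

    Writes every stage artifact plus a manifest into ``outdir`` and returns
    the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = run_config or RunConfig(seed=seed)
    sim = sim_config or SimConfig()
    artifacts = {}

    logger.info("simulating %d frames", sim.n_frames)
    truth = simulate_events(sim, seed)
    traces, _ = render_roi_traces(truth, sim, seed)
    write_roi_traces(traces, outdir / "traces.csv")
    write_event_table(truth.events, outdir / "truth_events.csv")
    artifacts["traces"] = "traces.csv"
    artifacts["truth_events"] = "truth_events.csv"

    logger.info("classifying with backbone %s", run.backbone)
    result = classify_traces(traces, run)
    pd.DataFrame(
        {"frame": np.arange(len(result["series"])), "label": [str(l) for l in result["series"]]}
    ).to_csv(outdir / "labels.csv", index=False)
    write_event_table(result["events"], outdir / "events.csv")
    artifacts["labels"] = "labels.csv"
    artifacts["events"] = "events.csv"

    shifted = shift_events(truth.events, -run.baseline_window, result["norm9"].n_valid_frames)
    report = evaluate_events(result["events"], shifted, run.overlap_threshold)
    stats = {
        "evaluation": {
            k.value: {kk: vv for kk, vv in v.items()} for k, v in report.items()
        },
        "frequency_per_min": {
            k.value: v
            for k, v in event_frequency(
                result["events"], result["norm9"].n_valid_frames * traces.frame_interval_s
            ).items()
        },
        "transition_probabilities": transition_matrix(result["events"]).to_frame().to_dict(),
    }
    (outdir / "stats.json").write_text(json.dumps(stats, indent=2, default=_jsonify))
    artifacts["stats"] = "stats.json"

    logger.info("rendering and mapping a %d-frame movie", movie_frames)
    movie_sim = dataclasses.replace(sim, n_frames=movie_frames)
    movie_truth = simulate_events(movie_sim, seed + 10)
    movie, movie_gt = render_volume_movie(movie_truth, movie_sim, seed + 10)
    vdff = voxel_dff(movie, run.baseline_window, run.clip_value, nonpositive="floor")
    series = movie_gt.frame_labels[run.baseline_window :]
    maps = {p: behavior_map(vdff, series, p) for p in PATTERNS}
    dom = dominant_map(maps, run.r_display_threshold)
    np.save(outdir / "dominant_map.npy", dom)
    import tifffile

    tifffile.imwrite(
        outdir / "behavior_maps.tif",
        np.stack([maps[p] for p in PATTERNS]).astype(np.float32),
    )
    artifacts["behavior_maps"] = "behavior_maps.tif"
    artifacts["dominant_map"] = "dominant_map.npy"

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(run, sim, seed),
        "stages": [
            "simulate",
            "preprocess",
            "windows",
            "features",
            "classify",
            "events",
            "stats",
            "map",
        ],
        "artifacts": artifacts,
        "evaluation": stats["evaluation"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonify))
    return manifest


def shift_events(events: pd.DataFrame, offset: int, n_frames: int) -> pd.DataFrame:
    """Shift event frame spans (e.g. into valid-frame coordinates) and clip."""
    rows = []
    for _, ev in events.iterrows():
        s = int(ev["start_frame"]) + offset
        e = int(ev["end_frame"]) + offset
        s2, e2 = max(s, 0), min(e, n_frames)
        if e2 <= s2:
            continue
        row = dict(ev)
        row["start_frame"], row["end_frame"] = s2, e2
        rows.append(row)
    return make_event_table(rows)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, MotorLabel):
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
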