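"""Synthetic fictive-locomotion generator with ground truth.

Emulates the statistical structure the classifier assumes: a semi-Markov
state sequence over {AT, BW, FW, PT, QS} with biased transitions (backward
waves tend to follow anterior bursts and forward waves posterior bursts,
and forward/backward waves never follow each other directly), lognormal
dwell times near the durations observed in isolated nerve cords, segmental
activity templates (travelling Gaussian bumps for waves, multi-segment
plateaus for bursts, left/right-asymmetric anterior bursts), slow
exponential photobleaching, and Gaussian shot-like noise.  A volumetric
renderer places ellipsoidal hemisegmental units on a small lattice and
plants one extra unit that is active only during backward waves — the
desk-scale analogue of a backward-specific interneuron that correlation
mapping should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .io import ROI_ORDER_18, SEGMENTS, RoiTraceSet, VolumeMovie, make_event_table
from .labels import MARKOV_STATES, MotorLabel

#: Biased transition matrix over (AT, BW, FW, PT, QS); rows sum to 1, zero
#: diagonal (the generator never emits two consecutive events of one class),
#: no direct FW<->BW transitions.
DEFAULT_TRANSITIONS: Dict[str, Dict[str, float]] = {
    "AT": {"BW": 0.6, "PT": 0.2, "QS": 0.2},
    "BW": {"AT": 0.6, "PT": 0.1, "QS": 0.3},
    "FW": {"PT": 0.6, "AT": 0.1, "QS": 0.3},
    "PT": {"FW": 0.6, "AT": 0.2, "QS": 0.2},
    "QS": {"AT": 0.25, "BW": 0.25, "FW": 0.25, "PT": 0.25},
}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Dwell means follow the durations reported for isolated-cord motor
    patterns (order 1.5-3 s); the frame interval matches the fastest
    imaging condition (180 ms per volume).  Amplitude is the peak dF/F a
    template adds on top of baseline; noise_sd is the Gaussian noise sd as
    a fraction of baseline fluorescence.
    """

    n_frames: int = 2048
    frame_interval_s: float = 0.18
    dwell_mean_s: Dict[str, float] = field(
        default_factory=lambda: {"AT": 2.2, "BW": 2.8, "FW": 2.3, "PT": 1.5, "QS": 2.9}
    )
    dwell_sd_s: Dict[str, float] = field(
        default_factory=lambda: {"AT": 0.6, "BW": 0.7, "FW": 0.6, "PT": 0.4, "QS": 1.0}
    )
    transitions: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITIONS.items()}
    )
    amplitude: float = 1.0  # peak dF/F added during an event
    wave_sigma_segments: float = 0.9  # width of the travelling bump
    at_segments: tuple = (0, 6)  # inclusive segment-index span of AT (T2..A4)
    pt_segments: tuple = (6, 8)  # inclusive span of PT (A4..A7)
    at_asym_range: tuple = (0.1, 0.5)  # weak-side amplitude ratio for AT
    noise_sd: float = 0.02  # fraction of baseline F
    bleach_tau_s: float = 600.0  # exponential photobleaching time constant
    baseline_f: float = 100.0
    ramp_frames: int = 1  # onset/offset ramp of burst envelopes
    # volumetric rendering
    movie_shape: tuple = (2, 32, 64)  # (z, y, x)
    unit_radius_vox: float = 2.5
    movie_baseline_f: float = 100.0

    def __post_init__(self) -> None:
        for state, row in self.transitions.items():
            total = sum(row.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"transition row {state} sums to {total}, not 1")
            if row.get(state, 0.0) != 0.0:
                raise ValueError("generator transition diagonal must be zero")
        for s, m in self.dwell_mean_s.items():
            if m <= 0 or self.dwell_sd_s[s] <= 0:
                raise ValueError("dwell distributions must be positive")


@dataclass
class GroundTruth:
    """Generated events, per-frame labels, and (for movies) unit voxel masks."""

    events: pd.DataFrame
    frame_labels: np.ndarray  # (n_frames,) of MotorLabel
    unit_masks: Optional[Dict[str, np.ndarray]] = None


def _lognormal_frames(rng, mean_s, sd_s, dt) -> int:
    mu = np.log(mean_s**2 / np.sqrt(mean_s**2 + sd_s**2))
    sigma = np.sqrt(np.log(1 + sd_s**2 / mean_s**2))
    dur = rng.lognormal(mu, sigma)
    return max(2, int(round(dur / dt)))


def simulate_events(config: SimConfig, seed: int = 0) -> GroundTruth:
    """Draw a semi-Markov event sequence covering ``n_frames`` frames."""
    rng = np.random.default_rng(seed)
    states = [s.value for s in MARKOV_STATES]
    state = states[rng.integers(len(states))]
    rows = []
    t = 0
    while t < config.n_frames:
        dur = _lognormal_frames(
            rng, config.dwell_mean_s[state], config.dwell_sd_s[state], config.frame_interval_s
        )
        end = min(t + dur, config.n_frames)
        rows.append(
            {
                "label": state,
                "start_frame": t,
                "end_frame": end,
                "duration_s": (end - t) * config.frame_interval_s,
                "intensity": np.nan,
                "mean_asymmetry": np.nan,
            }
        )
        t = end
        row = config.transitions[state]
        nxt = list(row.keys())
        state = nxt[rng.choice(len(nxt), p=np.array(list(row.values())))]
    events = make_event_table(rows)
    frame_labels = np.empty(config.n_frames, dtype=object)
    for _, ev in events.iterrows():
        frame_labels[int(ev["start_frame"]) : int(ev["end_frame"])] = MotorLabel(ev["label"])
    return GroundTruth(events=events, frame_labels=frame_labels)


def _event_envelope(length: int, ramp: int) -> np.ndarray:
    """Half-cosine onset/offset ramp over ``ramp`` frames (flat when ramp=0)."""
    env = np.ones(length)
    for k in range(min(ramp, length)):
        e = 0.5 - 0.5 * np.cos(np.pi * (k + 1) / (ramp + 1))
        env[k] = min(env[k], e)
        env[length - 1 - k] = min(env[length - 1 - k], e)
    return env


def _segment_activity(events: pd.DataFrame, config: SimConfig, rng) -> np.ndarray:
    """Per-hemisegment added dF/F (18, n_frames) from the event sequence."""
    seg_idx = np.arange(9, dtype=float)
    a9 = np.zeros((9, config.n_frames))
    side_factor = np.ones((2, config.n_frames))  # (L, R) multipliers
    for _, ev in events.iterrows():
        s, e = int(ev["start_frame"]), int(ev["end_frame"])
        L = e - s
        lab = ev["label"]
        env = _event_envelope(L, config.ramp_frames)
        if lab in ("FW", "BW"):
            # travelling Gaussian bump across the segment axis; FW runs
            # posterior (index 8) -> anterior (index 0), BW the reverse
            frac = np.arange(L) / max(L - 1, 1)
            center = 8.0 * (1.0 - frac) if lab == "FW" else 8.0 * frac
            bump = np.exp(
                -((seg_idx[:, None] - center[None, :]) ** 2)
                / (2 * config.wave_sigma_segments**2)
            )
            a9[:, s:e] += config.amplitude * bump * env[None, :]
        elif lab in ("AT", "PT"):
            lo, hi = config.at_segments if lab == "AT" else config.pt_segments
            a9[lo : hi + 1, s:e] += config.amplitude * env[None, :]
            if lab == "AT":
                weak = rng.uniform(*config.at_asym_range)
                weak_side = rng.integers(2)
                side_factor[weak_side, s:e] = weak
        # QS: nothing
    a18 = np.repeat(a9, 2, axis=0)
    a18[0::2] *= side_factor[0]  # left hemisegments
    a18[1::2] *= side_factor[1]  # right
    return a18


def render_roi_traces(
    truth: GroundTruth, config: SimConfig, seed: int = 0
) -> tuple:
    """Render 18 hemisegmental raw fluorescence traces for a truth sequence.

    Returns ``(RoiTraceSet, activity)`` where ``activity`` is the noise-free
    added dF/F per hemisegment, useful for oracle checks.
    """
    rng = np.random.default_rng(seed + 1)  # distinct stream from simulate_events
    a18 = _segment_activity(truth.events, config, rng)
    t = np.arange(config.n_frames)
    bleach = np.exp(-t * config.frame_interval_s / config.bleach_tau_s)
    F = config.baseline_f * bleach[None, :] * (1.0 + a18)
    F = F + rng.normal(0.0, config.noise_sd * config.baseline_f, size=F.shape)
    np.maximum(F, 0.01 * config.baseline_f, out=F)
    traces = RoiTraceSet(F, list(ROI_ORDER_18), config.frame_interval_s)
    return traces, a18


def _ellipsoid_mask(shape, center, radius) -> np.ndarray:
    _, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    _, cy, cx = center
    # units span the full (thin) z extent, disk-shaped in-plane
    in_plane = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2
    return np.broadcast_to(in_plane, shape).copy()


def render_volume_movie(
    truth: GroundTruth, config: SimConfig, seed: int = 0
) -> tuple:
    """Render a small volumetric movie plus voxel-level ground truth.

    Hemisegmental units are disks along the anterior->posterior (x) axis on
    two y-rows (left/right); one planted unit on the midline is active only
    during BW events.  Returns ``(VolumeMovie, GroundTruth)`` where the
    truth carries the unit masks under names like ``"A3_L"`` and
    ``"planted_BW"``.
    """
    rng = np.random.default_rng(seed + 2)
    z, y, x = config.movie_shape
    T = config.n_frames
    a18 = _segment_activity(truth.events, config, rng)
    t = np.arange(T)
    bleach = np.exp(-t * config.frame_interval_s / config.bleach_tau_s)

    masks: Dict[str, np.ndarray] = {}
    unit_traces: Dict[str, np.ndarray] = {}
    margin = config.unit_radius_vox + 1
    xs = np.linspace(margin, x - margin, 9)
    y_l, y_r = y * 0.3, y * 0.7
    for i, seg in enumerate(SEGMENTS):
        for j, (side, yc) in enumerate((("L", y_l), ("R", y_r))):
            m = _ellipsoid_mask((z, y, x), (0, yc, xs[i]), config.unit_radius_vox)
            masks[f"{seg}_{side}"] = m
            unit_traces[f"{seg}_{side}"] = a18[2 * i + j]
    # planted backward-specific unit on the midline, clear of the segment rows
    planted = _ellipsoid_mask((z, y, x), (0, y * 0.5, xs[2]), config.unit_radius_vox)
    bw_ind = np.array([1.0 if l is MotorLabel.BW else 0.0 for l in truth.frame_labels])
    masks["planted_BW"] = planted
    unit_traces["planted_BW"] = config.amplitude * bw_ind

    activity = np.zeros((T, z, y, x))
    for name, m in masks.items():
        activity[:, m] += unit_traces[name][:, None]
    F = config.movie_baseline_f * bleach[:, None, None, None] * (1.0 + activity)
    F += rng.normal(0.0, config.noise_sd * config.movie_baseline_f, size=F.shape)
    np.maximum(F, 0.01 * config.movie_baseline_f, out=F)
    movie = VolumeMovie(F, config.frame_interval_s)
    return movie, GroundTruth(
        events=truth.events, frame_labels=truth.frame_labels, unit_masks=masks
    )


def simulate_recording(config: SimConfig, seed: int = 0):
    """Convenience: events + 18-ROI traces in one call -> (traces, truth)."""
    truth = simulate_events(config, seed)
    traces, _ = render_roi_traces(truth, config, seed)
    return traces, truth
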