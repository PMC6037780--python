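"""Event-level statistics: frequency, intensity, asymmetry, Markov transitions,
and end-aligned average activity profiles.

All operations take the canonical event table (label, start_frame,
end_frame half-open, duration_s, intensity, mean_asymmetry) and the
normalized trace matrices.  Frames are indexed in dF/F (valid-frame)
coordinates throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .labels import MARKOV_STATES, MotorLabel, as_label
from .preprocess import NormTraceSet


def event_frequency(events: pd.DataFrame, total_time_s: float) -> Dict[MotorLabel, float]:
    """Events per minute for every motor label present (0 for absent ones)."""
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    counts = events["label"].value_counts() if len(events) else {}
    return {
        lab: 60.0 * float(counts.get(lab.value, 0)) / total_time_s for lab in MotorLabel
    }


def event_intensity(event, norm: NormTraceSet) -> float:
    """Maximum normalized fluorescence change over all ROIs during the event."""
    start, end = int(event["start_frame"]), int(event["end_frame"])
    if start < 0 or end > norm.n_valid_frames or end <= start:
        raise ValueError(f"event span [{start}, {end}) outside trace range")
    return float(norm.values[:, start:end].max())


def asymmetry_index(frame: int, norm18: NormTraceSet) -> float:
    """|max left - max right| / max overall at one frame; NaN when all zero.

    0 means bilaterally symmetric activity, 1 means fully one-sided.
    """
    if norm18.n_rois != 18:
        raise ValueError("asymmetry_index needs 18 hemisegmental ROIs")
    col = norm18.values[:, frame]
    left = np.array([v for v, (seg, side) in zip(col, norm18.roi_ids) if side == "L"])
    right = np.array([v for v, (seg, side) in zip(col, norm18.roi_ids) if side == "R"])
    m_all = col.max()
    if m_all == 0:
        return float("nan")
    return float(abs(left.max() - right.max()) / m_all)


def event_mean_asymmetry(event, norm18: NormTraceSet) -> float:
    """Mean asymmetry index over the frames of one event (NaN frames skipped)."""
    start, end = int(event["start_frame"]), int(event["end_frame"])
    vals = [asymmetry_index(t, norm18) for t in range(start, end)]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class TransitionMatrix:
    """Row-stochastic transitions between consecutive events."""

    states: Sequence[MotorLabel]
    counts: np.ndarray  # (k, k) int
    probabilities: np.ndarray  # (k, k); rows with no outgoing events are NaN
    defined_rows: np.ndarray  # (k,) bool

    def to_frame(self) -> pd.DataFrame:
        names = [s.value for s in self.states]
        return pd.DataFrame(self.probabilities, index=names, columns=names)


def transition_matrix(
    events: pd.DataFrame, states: Sequence = MARKOV_STATES
) -> TransitionMatrix:
    """Markov transition matrix over consecutive events.

    Unlabeled (UL) events and events outside ``states`` are dropped first;
    the remaining sequence is re-concatenated, so removing an intervening
    state can create same-state transitions (e.g. QS -> QS).
    """
    states = [as_label(s) for s in states]
    if MotorLabel.UL in states:
        raise ValueError("UL cannot be a Markov state")
    k = len(states)
    index = {s.value: i for i, s in enumerate(states)}
    seq = [index[lab] for lab in events.sort_values("start_frame")["label"] if lab in index]
    counts = np.zeros((k, k), dtype=int)
    if len(seq) < 2:
        warnings.warn("fewer than 2 retained events; empty transition matrix")
    else:
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    probs = np.full((k, k), np.nan)
    probs[defined] = counts[defined] / row_sums[defined, None]
    return TransitionMatrix(states=states, counts=counts, probabilities=probs, defined_rows=defined)


@dataclass
class AlignedProfile:
    """Per-class mean activity aligned on event end points."""

    profiles: Dict[MotorLabel, np.ndarray]  # class -> (n_rois, n_aligned_frames)
    n_events: Dict[MotorLabel, int]
    duration_mean_s: Dict[MotorLabel, float]
    duration_sd_s: Dict[MotorLabel, float]
    frames_before: int
    frames_after: int


def aligned_average(
    events: pd.DataFrame,
    traces: NormTraceSet,
    window_before_s: float = 4.0,
    window_after_s: float = 1.0,
    classes: Optional[Sequence] = None,
) -> AlignedProfile:
    """Average trace segments anchored at each event's end frame.

    Segments that would run past the recording edges are excluded.  Also
    reports the mean +/- sd duration per class in seconds.
    """
    dt = traces.frame_interval_s
    nb = int(round(window_before_s / dt))
    na = int(round(window_after_s / dt))
    classes = [as_label(c) for c in (classes or MARKOV_STATES)]
    profiles: Dict[MotorLabel, np.ndarray] = {}
    n_events: Dict[MotorLabel, int] = {}
    d_mean: Dict[MotorLabel, float] = {}
    d_sd: Dict[MotorLabel, float] = {}
    T = traces.n_valid_frames
    for cls in classes:
        rows = events[events["label"] == cls.value]
        segments = []
        for _, ev in rows.iterrows():
            end = int(ev["end_frame"])
            if end - nb < 0 or end + na > T:
                continue
            segments.append(traces.values[:, end - nb : end + na])
        if not segments:
            if len(rows):
                warnings.warn(f"no complete aligned segment for class {cls.value}")
            continue
        profiles[cls] = np.mean(segments, axis=0)
        n_events[cls] = len(segments)
        durs = rows["duration_s"].to_numpy(dtype=float)
        d_mean[cls] = float(durs.mean())
        d_sd[cls] = float(durs.std())
    return AlignedProfile(
        profiles=profiles,
        n_events=n_events,
        duration_mean_s=d_mean,
        duration_sd_s=d_sd,
        frames_before=nb,
        frames_after=na,
    )
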