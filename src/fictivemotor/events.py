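"""Per-frame label series, event extraction and hit / false-alarm scoring.

Window labels are expanded back to a full-length per-frame label series:
frame t takes the label of the window centered at t, and the 4 frames at
each edge (which no window centre covers) inherit the nearest window's
label.  Maximal runs of identical labels then become events, and predicted
events are scored against ground truth by interval overlap.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .io import make_event_table
from .labels import PATTERNS, MotorLabel, as_label
from .motor_stats import event_intensity, event_mean_asymmetry
from .preprocess import NormTraceSet


def window_labels_to_series(
    window_labels: Sequence,
    centers: np.ndarray,
    n_valid_frames: int,
    window_size: int = 8,
) -> np.ndarray:
    """Expand per-window labels to a per-frame series with edge compensation.

    With ``n`` windows centered at ``window_size//2 .. n_valid_frames -
    window_size//2 - 1``, the output has ``n + window_size`` frames: the
    first ``window_size//2`` frames copy the first window's label and the
    last ``window_size//2`` copy the last window's.
    """
    labels = [as_label(l) for l in window_labels]
    centers = np.asarray(centers)
    if len(labels) != len(centers):
        raise ValueError("window labels and centers differ in length")
    if len(labels) + window_size != n_valid_frames:
        raise ValueError(
            f"{len(labels)} windows cannot cover {n_valid_frames} frames "
            f"with window size {window_size}"
        )
    half = window_size // 2
    expected = np.arange(len(labels)) + half
    if not np.array_equal(centers, expected):
        raise ValueError("window centers inconsistent with the windowing convention")
    series = np.empty(n_valid_frames, dtype=object)
    series[half : half + len(labels)] = labels
    series[:half] = labels[0]
    series[half + len(labels) :] = labels[-1]
    return series


def enforce_min_duration(series: np.ndarray, min_frames: int) -> np.ndarray:
    """Absorb label runs shorter than ``min_frames`` into a longer neighbour.

    Window-level classification flickers near event boundaries, producing
    1-2-frame label fragments far shorter than any real motor pattern.
    Repeatedly the shortest offending run is merged into whichever adjacent
    run is longer, until every run reaches the minimum (or one run covers
    the series).  ``min_frames <= 1`` is a no-op.
    """
    if min_frames <= 1:
        return np.asarray(series, dtype=object)
    out = list(series)

    def runs():
        rr = []
        s = 0
        for t in range(1, len(out) + 1):
            if t == len(out) or out[t] != out[s]:
                rr.append((s, t))
                s = t
        return rr

    while True:
        rr = runs()
        if len(rr) == 1:
            break
        shorts = [(e - s, i) for i, (s, e) in enumerate(rr) if e - s < min_frames]
        if not shorts:
            break
        _, i = min(shorts)
        s, e = rr[i]
        left = rr[i - 1] if i > 0 else None
        right = rr[i + 1] if i < len(rr) - 1 else None
        if left is None:
            tgt = right
        elif right is None:
            tgt = left
        else:
            tgt = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        fill = out[tgt[0]]
        for t in range(s, e):
            out[t] = fill
    return np.array(out, dtype=object)


def extract_events(
    series: np.ndarray,
    frame_interval_s: float,
    norm: Optional[NormTraceSet] = None,
    norm18: Optional[NormTraceSet] = None,
) -> pd.DataFrame:
    """Run-length encode a label series into an event table.

    Every maximal run of one label becomes an event (QS and UL runs
    included).  ``intensity`` is filled from ``norm`` (max dF_norm over all
    ROIs and frames of the event) and ``mean_asymmetry`` from the 18-ROI
    ``norm18`` when given, else NaN.
    """
    rows = []
    n = len(series)
    start = 0
    for t in range(1, n + 1):
        if t == n or series[t] != series[start]:
            ev = {
                "label": as_label(series[start]).value,
                "start_frame": start,
                "end_frame": t,
                "duration_s": (t - start) * frame_interval_s,
                "intensity": np.nan,
                "mean_asymmetry": np.nan,
            }
            if norm is not None:
                ev["intensity"] = event_intensity(ev, norm)
            if norm18 is not None:
                ev["mean_asymmetry"] = event_mean_asymmetry(ev, norm18)
            rows.append(ev)
            start = t
    return make_event_table(rows)


def events_to_series(events: pd.DataFrame, n_frames: Optional[int] = None) -> np.ndarray:
    """Inverse of :func:`extract_events` for gap-free tables (gaps become UL)."""
    if len(events) == 0:
        return np.full(n_frames or 0, MotorLabel.UL, dtype=object)
    n = n_frames if n_frames is not None else int(events["end_frame"].max())
    series = np.full(n, MotorLabel.UL, dtype=object)
    for _, ev in events.iterrows():
        series[int(ev["start_frame"]) : int(ev["end_frame"])] = as_label(ev["label"])
    return series


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def evaluate_events(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    overlap_threshold: float = 0.5,
    classes: Sequence = PATTERNS,
) -> Dict[MotorLabel, dict]:
    """Per-class hit and false-alarm rates by interval overlap.

    A truth event is a *hit* when some predicted event of the same class
    overlaps at least ``overlap_threshold`` of the truth span.  A predicted
    event is a *false alarm* when it overlaps no truth event of its class.
    A class with no truth events has an undefined hit rate (None, not 0);
    likewise the false-alarm rate when nothing was predicted.
    """
    out: Dict[MotorLabel, dict] = {}
    for cls in classes:
        cls = as_label(cls)
        t_rows = truth[truth["label"] == cls.value]
        p_rows = pred[pred["label"] == cls.value]
        hits = 0
        for _, tv in t_rows.iterrows():
            span = tv["end_frame"] - tv["start_frame"]
            for _, pv in p_rows.iterrows():
                if (
                    _overlap(tv["start_frame"], tv["end_frame"], pv["start_frame"], pv["end_frame"])
                    >= overlap_threshold * span
                ):
                    hits += 1
                    break
        false_alarms = 0
        for _, pv in p_rows.iterrows():
            if not any(
                _overlap(tv["start_frame"], tv["end_frame"], pv["start_frame"], pv["end_frame"]) > 0
                for _, tv in t_rows.iterrows()
            ):
                false_alarms += 1
        out[cls] = {
            "n_truth": len(t_rows),
            "n_pred": len(p_rows),
            "hits": hits,
            "false_alarms": false_alarms,
            "hit_rate": hits / len(t_rows) if len(t_rows) else None,
            "false_alarm_rate": false_alarms / len(p_rows) if len(p_rows) else None,
        }
    return out
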