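"""Raw fluorescence -> rectified dF/F -> [0, 1] normalized segmental traces.

The baseline for frame t is the mean raw fluorescence of the preceding
``baseline_window`` frames (default 16), so the first ``baseline_window``
frames have no defined baseline and are dropped.  dF/F is rectified: the
calcium indicator reports activity while its signal is *rising*, and a
running baseline tracks slow photobleaching, so only positive excursions are
meaningful.  Hemisegmental (18-ROI) traces are compressed to 9 segmental
traces by the left/right maximum so that activity on either side is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import ROI_ORDER_9, SEGMENTS, RoiTraceSet


@dataclass
class DffTraceSet:
    """Rectified dF/F per ROI, frames ``baseline_window..n_frames-1`` of the raw trace."""

    values: np.ndarray  # (n_rois, n_valid_frames), >= 0
    roi_ids: Sequence[tuple]
    frame_interval_s: float
    first_valid_frame: int
    clip_value: Optional[float] = None

    @property
    def n_valid_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NormTraceSet:
    """dF/F min-max scaled into [0, 1] (or raw dF/F when ``normalized=False``)."""

    values: np.ndarray  # (n_rois, n_valid_frames)
    roi_ids: Sequence[tuple]
    frame_interval_s: float
    first_valid_frame: int
    normalized: bool = True

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_valid_frames(self) -> int:
        return self.values.shape[1]


def running_baseline(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of the ``window`` preceding frames, for frames ``window..T-1``.

    ``values`` is (..., T); the result is (..., T - window) where entry t is
    the mean of frames ``t .. t+window-1`` of the input, i.e. the baseline of
    input frame ``t + window``.
    """
    values = np.asarray(values, dtype=float)
    csum = np.cumsum(values, axis=-1)
    total = csum[..., window - 1 : -1].copy()
    total[..., 1:] -= csum[..., : -window - 1]
    return total / window


def compute_dff(
    traces: RoiTraceSet,
    baseline_window: int = 16,
    clip_value: Optional[float] = None,
) -> DffTraceSet:
    """Rectified dF/F against a running-mean baseline.

    For each ROI and frame t >= ``baseline_window``::

        F_base(t) = mean(F(t - baseline_window) .. F(t - 1))
        dF/F(t)   = max(0, F(t) / F_base(t) - 1)

    Values above ``clip_value`` (if given) are capped.  The first
    ``baseline_window`` frames are dropped from the output.
    """
    F = np.asarray(traces.values, dtype=float)
    if traces.n_frames <= baseline_window:
        raise ValueError(
            f"recording too short: {traces.n_frames} frames, "
            f"baseline needs > {baseline_window}"
        )
    if (F <= 0).any():
        raise ValueError("nonpositive fluorescence; dF/F requires F > 0")
    base = running_baseline(F, baseline_window)
    dff = np.maximum(F[:, baseline_window:] / base - 1.0, 0.0)
    if clip_value is not None:
        np.minimum(dff, clip_value, out=dff)
    return DffTraceSet(
        values=dff,
        roi_ids=list(traces.roi_ids),
        frame_interval_s=traces.frame_interval_s,
        first_valid_frame=baseline_window,
        clip_value=clip_value,
    )


def minmax_normalize(dff: DffTraceSet) -> NormTraceSet:
    """Scale the whole dF/F matrix into [0, 1] by a global min-max transform.

    The scaling is global (not per ROI) so that inter-segment intensity
    ratios survive; a constant matrix maps to all zeros.
    """
    v = np.asarray(dff.values, dtype=float)
    lo, hi = v.min(), v.max()
    out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return NormTraceSet(
        values=out,
        roi_ids=list(dff.roi_ids),
        frame_interval_s=dff.frame_interval_s,
        first_valid_frame=dff.first_valid_frame,
        normalized=True,
    )


def compress_lr(norm18: NormTraceSet) -> NormTraceSet:
    """Compress 18 hemisegmental traces to 9 segmental traces by the L/R maximum."""
    if norm18.n_rois != 18:
        raise ValueError("compress_lr expects 18 hemisegmental ROIs")
    ids = list(norm18.roi_ids)
    out = np.empty((9, norm18.values.shape[1]), dtype=float)
    for i, seg in enumerate(SEGMENTS):
        try:
            left = ids.index((seg, "L"))
            right = ids.index((seg, "R"))
        except ValueError as exc:
            raise ValueError(f"unpaired hemisegment for {seg}") from exc
        out[i] = np.maximum(norm18.values[left], norm18.values[right])
    return NormTraceSet(
        values=out,
        roi_ids=list(ROI_ORDER_9),
        frame_interval_s=norm18.frame_interval_s,
        first_valid_frame=norm18.first_valid_frame,
        normalized=norm18.normalized,
    )


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Optional centered moving-average smoother (off by default in the pipeline)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    kernel = np.ones(width) / width
    return np.apply_along_axis(lambda m: np.convolve(m, kernel, mode="same"), -1, values)
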