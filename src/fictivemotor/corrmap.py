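"""Voxel-wise Pearson correlation mapping.

Behavior maps correlate each voxel's rectified dF/F with the 0/1 indicator
of one motor pattern; the dominant map assigns each voxel the pattern of
its highest correlation (above a display threshold, default 0.1); ROI maps
correlate voxels with the dF/F of a seed region and refine the region to
the voxels with r >= 0.05.  The label series and the voxel dF/F share the
same valid-frame origin (both drop the first ``baseline_window`` frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .io import VolumeMovie
from .labels import PATTERNS, MotorLabel, as_label
from .preprocess import running_baseline

#: Fixed pattern order used for dominant maps (also the tie-break order).
DOMINANT_ORDER = tuple(PATTERNS)


@dataclass
class CorrelationMap:
    """Per-pattern r volumes and the derived dominant-pattern assignment."""

    r_volumes: Dict[MotorLabel, np.ndarray]
    threshold: float
    dominant: Optional[np.ndarray] = None  # int volume; -1 = unassigned


@dataclass
class RefinedRoi:
    """Voxel mask refined by correlation with a seed trace, plus its summed F(t)."""

    mask: np.ndarray  # boolean (z, y, x)
    trace: np.ndarray  # (n_frames,) summed raw F over the mask
    threshold: float

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("refined ROI mask is empty")


def voxel_dff(
    movie: VolumeMovie,
    baseline_window: int = 16,
    clip_value: Optional[float] = None,
    nonpositive: str = "error",
) -> np.ndarray:
    """Rectified running-baseline dF/F per voxel; output (t - bw, z, y, x).

    ``nonpositive`` controls voxels that are not strictly positive:
    ``"error"`` raises, ``"floor"`` lifts them to a small positive value
    (useful for dark background voxels in synthetic movies).
    """
    V = np.asarray(movie.voxels, dtype=float)
    if V.shape[0] <= baseline_window:
        raise ValueError("movie too short for the baseline window")
    if (V <= 0).any():
        if nonpositive == "error":
            raise ValueError("nonpositive voxel intensities; use nonpositive='floor'")
        if nonpositive != "floor":
            raise ValueError("nonpositive must be 'error' or 'floor'")
        V = np.maximum(V, 1e-6 * max(V.max(), 1.0))
    flat = V.reshape(V.shape[0], -1).T  # (n_voxels, t)
    base = running_baseline(flat, baseline_window)
    dff = np.maximum(flat[:, baseline_window:] / base - 1.0, 0.0)
    if clip_value is not None:
        np.minimum(dff, clip_value, out=dff)
    return dff.T.reshape(-1, *V.shape[1:])


def _pearson_vs_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X (T, V) against y (T,); NaN where degenerate."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ss_y = (yc**2).sum()
    Xc = X - X.mean(axis=0)
    num = Xc.T @ yc
    ss_x = (Xc**2).sum(axis=0)
    # exactly-constant voxels are degenerate even when mean-subtraction
    # leaves rounding residue in ss_x
    ss_x[np.ptp(X, axis=0) == 0] = 0.0
    den = np.sqrt(ss_x * ss_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)  # guards rounding; NaN passes through


def behavior_map(
    vdff: np.ndarray, series: np.ndarray, pattern: "str | MotorLabel"
) -> np.ndarray:
    """Per-voxel Pearson r between dF/F and the binary indicator of a pattern.

    ``vdff`` is (t, z, y, x) from :func:`voxel_dff`; ``series`` is the
    per-frame label series over the same valid frames.  Zero-variance
    voxels, and a constant indicator, yield NaN.
    """
    pattern = as_label(pattern)
    if len(series) != vdff.shape[0]:
        raise ValueError("label series not aligned with voxel dF/F frames")
    indicator = np.array([1.0 if as_label(l) is pattern else 0.0 for l in series])
    if indicator.min() == indicator.max():
        warnings.warn(f"label vector for {pattern.value} is constant; map undefined")
        return np.full(vdff.shape[1:], np.nan)
    flat = vdff.reshape(vdff.shape[0], -1)
    r = _pearson_vs_vector(flat, indicator)
    return r.reshape(vdff.shape[1:])


def dominant_map(
    maps: Dict["str | MotorLabel", np.ndarray],
    threshold: float = 0.1,
    order: Sequence = DOMINANT_ORDER,
) -> np.ndarray:
    """Argmax pattern per voxel where max r > threshold, else -1.

    Ties are broken by the fixed pattern order (first of the tied wins);
    the integer codes index into ``order``.
    """
    order = [as_label(p) for p in order]
    stack = np.stack([np.asarray(maps[p]) for p in order])
    if any(np.asarray(maps[p]).shape != stack.shape[1:] for p in order):
        raise ValueError("correlation maps have mismatched shapes")
    filled = np.where(np.isnan(stack), -np.inf, stack)
    best = filled.argmax(axis=0)
    best_r = filled.max(axis=0)
    return np.where(best_r > threshold, best, -1)


def roi_map(
    movie: VolumeMovie,
    seed_mask: np.ndarray,
    baseline_window: int = 16,
    r_threshold: float = 0.05,
    clip_value: Optional[float] = None,
    nonpositive: str = "error",
    n_iterations: int = 1,
):
    """Seed-ROI correlation map with thresholded refinement.

    The seed trace is the sum of raw F over the seed voxels, converted to
    rectified dF/F; each voxel's dF/F is correlated against it, and the
    refined ROI keeps the voxels with r >= ``r_threshold`` (single pass by
    default; ``n_iterations > 1`` repeats refine -> re-correlate).  Returns
    ``(r_volume, RefinedRoi)``.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != movie.voxels.shape[1:]:
        raise ValueError("seed mask shape does not match movie volume")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    vdff = voxel_dff(movie, baseline_window, clip_value, nonpositive)
    flat_raw = movie.voxels.reshape(movie.n_frames, -1)
    flat_dff = vdff.reshape(vdff.shape[0], -1)

    mask = seed_mask
    r = None
    for _ in range(max(1, n_iterations)):
        seed_trace = flat_raw[:, mask.ravel()].sum(axis=1)
        base = running_baseline(seed_trace, baseline_window)
        seed_dff = np.maximum(seed_trace[baseline_window:] / base - 1.0, 0.0)
        if seed_dff.max() == seed_dff.min():
            raise ValueError("degenerate (constant) seed trace")
        r = _pearson_vs_vector(flat_dff, seed_dff)
        new_mask = (np.nan_to_num(r, nan=-1.0) >= r_threshold).reshape(seed_mask.shape)
        if not new_mask.any():
            warnings.warn("no voxel reached the refinement threshold; keeping seed")
            new_mask = mask
            break
        mask = new_mask
    refined_trace = flat_raw[:, mask.ravel()].sum(axis=1)
    return r.reshape(seed_mask.shape), RefinedRoi(
        mask=mask, trace=refined_trace, threshold=r_threshold
    )
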