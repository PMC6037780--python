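"""Ward clustering of window features and cluster -> motor-pattern labeling.

Windows are grouped by hierarchical agglomerative clustering (Ward's
method, Euclidean distance) and the tree is cut at a fixed number of
clusters (default 25).  Each cluster is then summarized by the mean of its
raw 9x8 window tensors, and the mean image is mapped to a motor-pattern
label either automatically (intensity / propagation-slope / mass-fraction
heuristics) or by explicit manual override, mirroring the visual
inspection of average cluster images that the automated rules replace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .features import FeatureMatrix
from .labels import MotorLabel, as_label

logger = logging.getLogger("fictivemotor")

#: Anterior zone T2..A4 and posterior zone A4..A7 as segment-index slices
#: (A4, index 6, belongs to both; ties go to the zone with the greater mass).
ANTERIOR_SLICE = slice(0, 7)
POSTERIOR_SLICE = slice(6, 9)


@dataclass
class ClusterAssignment:
    """Flat cluster ids per window plus the full merge tree."""

    labels: np.ndarray  # (n_windows,) ints in [0, n_clusters)
    linkage: np.ndarray  # scipy linkage matrix (n_windows - 1, 4)
    n_clusters: int

    def __post_init__(self) -> None:
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.n_clusters:
            raise ValueError("cluster ids out of range")


@dataclass
class LabelThresholds:
    """Auto-labeling thresholds (calibrated on the synthetic generator).

    ``qs_intensity``: mean window intensity below which a window is QS.
    ``wave_slope``: minimum |centre-of-mass drift| in segments/frame for a
    propagating wave.  ``at_fraction``/``pt_fraction``: minimum share of
    total intensity in the anterior (T2-A4) / posterior (A4-A7) zone.
    ``cos_continuity``/``gap_norm``: adjacent-column cosine similarity and
    minimum column norm that define the coherent sub-window around the
    window centre (a window straddling an event boundary is classified by
    the side its centre frame belongs to).  ``vote_purity``: minimum
    fraction of agreeing member windows for a cluster's majority label to
    override the per-window labels.
    """

    qs_intensity: float = 0.05
    wave_slope: float = 0.25
    at_fraction: float = 0.7
    pt_fraction: float = 0.7
    cos_continuity: float = 0.5
    gap_norm: float = 0.1
    vote_purity: float = 0.8


@dataclass
class ClusterLabelMap:
    """cluster id -> motor label, with per-cluster diagnostics."""

    labels: Dict[int, MotorLabel]
    mean_windows: Dict[int, np.ndarray]
    stats: Dict[int, dict] = field(default_factory=dict)

    def window_labels(self, assignment: ClusterAssignment) -> np.ndarray:
        """Per-window labels (object array of MotorLabel)."""
        return np.array(
            [self.labels.get(int(c), MotorLabel.UL) for c in assignment.labels],
            dtype=object,
        )


def cluster_windows(features: FeatureMatrix, n_clusters: int) -> ClusterAssignment:
    """Ward's-method agglomerative clustering cut at ``n_clusters``."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    X = np.asarray(features.vectors, dtype=float)
    if n_clusters > X.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds {X.shape[0]} windows")
    Z = linkage(X, method="ward")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return ClusterAssignment(labels=flat, linkage=Z, n_clusters=int(flat.max()) + 1)


def mean_cluster_windows(
    assignment: ClusterAssignment, tensors: np.ndarray
) -> Dict[int, np.ndarray]:
    """Arithmetic mean of the raw window tensors of each cluster."""
    if len(tensors) != len(assignment.labels):
        raise ValueError("assignment does not cover the window tensors")
    means: Dict[int, np.ndarray] = {}
    for cid in range(assignment.n_clusters):
        mask = assignment.labels == cid
        if not mask.any():
            warnings.warn(f"cluster {cid} is empty; excluded from labeling")
            continue
        means[cid] = tensors[mask].mean(axis=0)
    return means


def window_signature(mean_window: np.ndarray) -> dict:
    """Diagnostics of a mean window: intensity, zone fractions, drift slope.

    The slope is the linear-regression coefficient of the intensity
    centre of mass (in segment index, anterior = 0) on the frame index
    within the window; negative slope = anterior-ward propagation (FW).
    """
    w = np.asarray(mean_window, dtype=float)
    n_seg, n_t = w.shape
    total = w.sum()
    intensity = w.mean()
    if total <= 0:
        return {
            "intensity": intensity,
            "anterior_fraction": np.nan,
            "posterior_fraction": np.nan,
            "com_slope": 0.0,
        }
    ant = w[ANTERIOR_SLICE].sum()
    post = w[POSTERIOR_SLICE].sum()
    col_mass = w.sum(axis=0)
    seg_idx = np.arange(n_seg, dtype=float)
    valid = col_mass > 0.05 * col_mass.max()
    slope = 0.0
    if valid.sum() >= 3:
        com = (seg_idx[:, None] * w[:, valid]).sum(axis=0) / col_mass[valid]
        t = np.arange(n_t, dtype=float)[valid]
        slope = float(np.polyfit(t, com, 1)[0])
    return {
        "intensity": float(intensity),
        "anterior_fraction": float(ant / total),
        "posterior_fraction": float(post / total),
        "com_slope": slope,
    }


def _rule_label(sub: np.ndarray, th: LabelThresholds) -> MotorLabel:
    """Ordered rules on a (possibly truncated) window: QS, wave, burst, UL.

    Near-zero intensity -> QS; strong centre-of-mass drift -> FW
    (anterior-ward) or BW (posterior-ward); intensity concentrated in the
    anterior zone -> AT, in the posterior zone -> PT (if both zone rules
    fire, the heavier zone wins); otherwise UL.  Wave rules precede burst
    rules because propagation is the more specific signature.
    """
    total = sub.sum()
    if total <= 0 or sub.mean() < th.qs_intensity:
        return MotorLabel.QS
    n_seg = sub.shape[0]
    col = sub.sum(axis=0)
    seg_idx = np.arange(n_seg, dtype=float)
    valid = col > 0.05 * col.max()
    slope = 0.0
    if valid.sum() >= 3:
        com = (seg_idx[:, None] * sub[:, valid]).sum(axis=0) / col[valid]
        t = np.arange(sub.shape[1], dtype=float)[valid]
        slope = float(np.polyfit(t, com, 1)[0])
    if abs(slope) > th.wave_slope:
        return MotorLabel.FW if slope < 0 else MotorLabel.BW
    ant = sub[ANTERIOR_SLICE].sum()
    post = sub[POSTERIOR_SLICE].sum()
    at_hit = ant / total > th.at_fraction
    pt_hit = post / total > th.pt_fraction
    if at_hit and pt_hit:
        return MotorLabel.AT if ant >= post else MotorLabel.PT
    if at_hit:
        return MotorLabel.AT
    if pt_hit:
        return MotorLabel.PT
    return MotorLabel.UL


def classify_window(window: np.ndarray, thresholds: Optional[LabelThresholds] = None) -> MotorLabel:
    """Label one window by the rules, restricted to its coherent centre.

    A window whose span straddles an event boundary mixes two patterns; the
    label belongs to the pattern at the centre frame.  The classifier grows
    a sub-window from the centre column outward while adjacent columns stay
    similar (cosine similarity above ``cos_continuity`` and column norms
    above ``gap_norm``) and applies the ordered rules to that sub-window.
    """
    th = thresholds or LabelThresholds()
    w = np.asarray(window, dtype=float)
    if w.mean() < th.qs_intensity:
        return MotorLabel.QS
    n_t = w.shape[1]
    c0 = n_t // 2
    norms = np.linalg.norm(w, axis=0)

    def connected(a: int, b: int) -> bool:
        if norms[a] < th.gap_norm or norms[b] < th.gap_norm:
            return False
        return float(w[:, a] @ w[:, b] / (norms[a] * norms[b])) > th.cos_continuity

    lo = c0
    while lo > 0 and connected(lo - 1, lo):
        lo -= 1
    hi = c0
    while hi < n_t - 1 and connected(hi, hi + 1):
        hi += 1
    sub = w[:, lo : hi + 1]
    if sub.mean() < th.qs_intensity and norms[c0] < th.gap_norm:
        return MotorLabel.QS
    return _rule_label(sub, th)


def auto_label_clusters(
    means: Mapping[int, np.ndarray],
    thresholds: Optional[LabelThresholds] = None,
) -> ClusterLabelMap:
    """Label clusters from their mean windows (rule classifier per mean)."""
    th = thresholds or LabelThresholds()
    labels: Dict[int, MotorLabel] = {}
    stats: Dict[int, dict] = {}
    for cid, mean_w in means.items():
        stats[cid] = window_signature(mean_w)
        labels[cid] = classify_window(mean_w, th)
    return ClusterLabelMap(labels=labels, mean_windows=dict(means), stats=stats)


def label_windows(
    assignment: ClusterAssignment,
    tensors: np.ndarray,
    thresholds: Optional[LabelThresholds] = None,
    overrides: Optional[Mapping[int, "str | MotorLabel"]] = None,
):
    """Per-window labels with purity-gated cluster voting.

    Every window is first classified by :func:`classify_window`.  Within
    each Ward cluster the majority label is taken; when at least
    ``vote_purity`` of the member windows agree, the majority overrides the
    individual labels (the cluster acts as a denoiser), otherwise the
    cluster is treated as mixed and its windows keep their own labels.
    Manual ``overrides`` force a label onto all windows of a cluster.

    Returns ``(window_labels, ClusterLabelMap)`` where the map records each
    cluster's majority label, mean window and vote fraction.
    """
    th = thresholds or LabelThresholds()
    if len(tensors) != len(assignment.labels):
        raise ValueError("assignment does not cover the window tensors")
    own = np.array([classify_window(w, th) for w in tensors], dtype=object)
    final = own.copy()
    labels: Dict[int, MotorLabel] = {}
    means: Dict[int, np.ndarray] = {}
    stats: Dict[int, dict] = {}
    for cid in range(assignment.n_clusters):
        mask = assignment.labels == cid
        if not mask.any():
            warnings.warn(f"cluster {cid} is empty; excluded from labeling")
            continue
        votes: Dict[MotorLabel, int] = {}
        for lab in own[mask]:
            votes[lab] = votes.get(lab, 0) + 1
        top, n = max(votes.items(), key=lambda kv: kv[1])
        labels[cid] = top
        means[cid] = tensors[mask].mean(axis=0)
        stats[cid] = dict(
            window_signature(means[cid]), vote_fraction=n / mask.sum(), n_windows=int(mask.sum())
        )
        if n / mask.sum() >= th.vote_purity:
            final[mask] = top
    label_map = ClusterLabelMap(labels=labels, mean_windows=means, stats=stats)
    if overrides:
        label_map = manual_label_clusters(label_map, overrides)
        for cid, lab in overrides.items():
            final[assignment.labels == int(cid)] = as_label(lab)
    return final, label_map


def manual_label_clusters(
    auto_map: ClusterLabelMap, overrides: Mapping[int, "str | MotorLabel"]
) -> ClusterLabelMap:
    """Apply manual overrides on top of the automatic labels."""
    labels = dict(auto_map.labels)
    for cid, lab in overrides.items():
        cid = int(cid)
        if cid not in labels:
            raise ValueError(f"unknown cluster id {cid}")
        labels[cid] = as_label(lab)
    return ClusterLabelMap(
        labels=labels, mean_windows=auto_map.mean_windows, stats=auto_map.stats
    )
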