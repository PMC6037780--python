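"""On-disk artifacts: ROI trace tables, volumetric movies, event tables, config.

Conventions
-----------
* All frame indices on disk are 0-based and spans are half-open ``[start, end)``.
* Trace tables are UTF-8 CSV with a header naming each ROI, e.g. ``A3_L`` for
  the left hemisegment of abdominal neuromere 3, or plain ``A3`` for a
  left/right-compressed segmental trace.
* Movies are multi-page TIFF; page order is t-major, then z (declared z depth).
* The frame interval is metadata supplied by the caller, never inferred.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .labels import MotorLabel, as_label

logger = logging.getLogger("fictivemotor")

#: Imaged neuromeres, anterior to posterior.
SEGMENTS = ("T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6", "A7")
SIDES = ("L", "R")

#: Canonical 18-ROI order: anterior->posterior, left before right per segment.
ROI_ORDER_18 = tuple((seg, side) for seg in SEGMENTS for side in SIDES)
ROI_ORDER_9 = tuple((seg, None) for seg in SEGMENTS)


def roi_name(seg: str, side: Optional[str]) -> str:
    return seg if side is None else f"{seg}_{side}"


@dataclass
class RoiTraceSet:
    """Raw fluorescence F(t), one row per ROI, one column per frame."""

    values: np.ndarray  # (n_rois, n_frames)
    roi_ids: Sequence[tuple]  # [(segment, side-or-None), ...]
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = [tuple(r) for r in self.roi_ids]
        if self.values.ndim != 2:
            raise ValueError("trace values must be 2-D (n_rois, n_frames)")
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("roi_ids length does not match trace rows")
        if self.n_rois not in (18, 9):
            raise ValueError(
                f"expected 18 hemisegmental or 9 segmental ROIs, got {self.n_rois}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("trace values must be finite")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        expected = ROI_ORDER_18 if self.n_rois == 18 else ROI_ORDER_9
        if tuple(self.roi_ids) != expected:
            raise ValueError(
                "ROIs must be ordered anterior->posterior (L before R): "
                f"expected {expected}, got {tuple(self.roi_ids)}"
            )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def roi_names(self) -> list:
        return [roi_name(seg, side) for seg, side in self.roi_ids]


@dataclass
class VolumeMovie:
    """Volumetric fluorescence movie, axis order (t, z, y, x)."""

    voxels: np.ndarray
    frame_interval_s: float
    spacing_um: Optional[tuple] = None  # optional (z, y, x) physical spacing

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("movie must be 4-D (t, z, y, x)")
        if not np.isfinite(self.voxels).all():
            raise ValueError("movie voxels must be finite")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]


@dataclass
class RunConfig:
    """All tunable analysis parameters with their defaults.

    ``clip_value`` caps rectified dF/F at 2 (appropriate for bright motoneuron
    drivers whose transients occasionally spike to implausible ratios); set it
    to ``None`` for dimmer reporters.  The auto-labeling thresholds were
    calibrated on the synthetic generator and are documented in the methods
    note.
    """

    baseline_window: int = 16  # frames of running baseline
    window_size: int = 8  # frames per x-t window
    image_side: int = 72  # pixels of the square window image
    clip_value: Optional[float] = 2.0  # dF/F cap, None to disable
    n_clusters: int = 25
    r_display_threshold: float = 0.1  # Pearson r for map display / dominance
    r_roi_threshold: float = 0.05  # Pearson r for ROI refinement
    backbone: str = "vgg16-random"
    tap_layer: str = "conv4_3"
    normalization: str = "imagenet"  # image preprocessing before the CNN
    theta_qs: float = 0.05  # mean-intensity floor below which a window is QS
    theta_wave: float = 0.25  # |centre-of-mass slope| (segments/frame) for waves
    theta_at: float = 0.7  # anterior mass fraction for AT
    theta_pt: float = 0.7  # posterior mass fraction for PT
    theta_cos: float = 0.5  # adjacent-column cosine continuity within one pattern
    theta_gap: float = 0.1  # column norm below which a column breaks continuity
    vote_purity: float = 0.8  # cluster majority needed to override window labels
    min_event_s: float = 0.9  # label runs shorter than this merge into neighbours
    overlap_threshold: float = 0.5  # fraction of a truth event a hit must cover
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_window", "window_size", "image_side", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.image_side % self.window_size != 0:
            raise ValueError("window_size must divide image_side")
        if self.clip_value is not None and self.clip_value <= 0:
            raise ValueError("clip_value must be positive or None")

    def save(self, path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# ROI trace tables


def _parse_roi_column(name: str) -> tuple:
    name = name.strip()
    if "_" in name:
        seg, _, side = name.partition("_")
        if seg not in SEGMENTS or side not in SIDES:
            raise ValueError(f"unrecognized ROI column {name!r}")
        return (seg, side)
    if name not in SEGMENTS:
        raise ValueError(f"unrecognized ROI column {name!r}")
    return (name, None)


def read_roi_traces(path, frame_interval_s: float) -> RoiTraceSet:
    """Read a delimited ROI trace table (one column per ROI, one row per frame).

    Columns are matched by name (``A3_L`` style for 18 hemisegmental ROIs,
    ``A3`` style for 9 compressed ROIs) and reordered into the canonical
    anterior->posterior, left-before-right order.
    """
    df = pd.read_csv(path)
    if len(df) < 2:
        raise ValueError("trace table must have at least 2 frames")
    ids = [_parse_roi_column(c) for c in df.columns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ROI columns in trace table")
    sides = {side for _, side in ids}
    if None in sides and len(sides) > 1:
        raise ValueError("mixed hemisegmental and compressed ROI columns")
    expected = ROI_ORDER_9 if sides == {None} else ROI_ORDER_18
    missing = set(expected) - set(ids)
    if missing:
        raise ValueError(
            "incomplete hemisegment set: missing "
            + ", ".join(sorted(roi_name(*m) for m in missing))
        )
    try:
        values = df.to_numpy(dtype=float).T
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in trace table: {exc}") from exc
    order = [ids.index(r) for r in expected]
    return RoiTraceSet(values[order], list(expected), frame_interval_s)


def write_roi_traces(traces: RoiTraceSet, path) -> None:
    df = pd.DataFrame(traces.values.T, columns=traces.roi_names)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Volume movies


def read_volume_movie(path, z: int, frame_interval_s: float) -> VolumeMovie:
    """Read a multi-page TIFF as a (t, z, y, x) movie with declared z depth."""
    if z < 1:
        raise ValueError("z must be >= 1")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim == 4:  # already (t, z, y, x)
        if pages.shape[1] != z:
            raise ValueError(f"movie has z={pages.shape[1]}, declared z={z}")
        return VolumeMovie(pages, frame_interval_s)
    if pages.ndim != 3:
        raise ValueError("unsupported TIFF layout for a volume movie")
    n_pages = pages.shape[0]
    if n_pages % z != 0:
        raise ValueError(f"page count {n_pages} not divisible by declared z={z}")
    voxels = pages.reshape(n_pages // z, z, *pages.shape[1:])
    return VolumeMovie(voxels, frame_interval_s)


def write_volume_movie(movie: VolumeMovie, path) -> None:
    t, z, y, x = movie.voxels.shape
    tifffile.imwrite(path, movie.voxels.reshape(t * z, y, x).astype(np.float32))


# ---------------------------------------------------------------------------
# Event tables

EVENT_COLUMNS = (
    "label",
    "start_frame",
    "end_frame",
    "duration_s",
    "intensity",
    "mean_asymmetry",
)


def make_event_table(rows: Optional[Sequence[dict]] = None) -> pd.DataFrame:
    """An empty (or pre-filled) event table with the canonical schema."""
    df = pd.DataFrame(list(rows or []), columns=list(EVENT_COLUMNS))
    df["label"] = df["label"].map(lambda v: as_label(v).value) if len(df) else df["label"]
    return df.astype(
        {
            "label": str,
            "start_frame": np.int64,
            "end_frame": np.int64,
            "duration_s": float,
            "intensity": float,
            "mean_asymmetry": float,
        }
    )


def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    df = df[list(EVENT_COLUMNS)].copy()
    for lab in df["label"]:
        as_label(lab)
    if (df["end_frame"] <= df["start_frame"]).any():
        raise ValueError("event with end_frame <= start_frame")
    ordered = df.sort_values("start_frame")
    if (ordered["start_frame"].to_numpy()[1:] < ordered["end_frame"].to_numpy()[:-1]).any():
        raise ValueError("overlapping events in table")
    return df


def write_event_table(df: pd.DataFrame, path) -> None:
    validate_event_table(df).to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        return make_event_table()
    df = validate_event_table(df)
    return make_event_table(df.to_dict("records"))


def configure_logging(level: str = "INFO") -> None:
    """Structured logging to stderr (used by the CLI)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
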