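"""Fixed-size x-t windows and their square 8-bit image encoding.

The 9-ROI normalized time series is decomposed into 8-frame windows: the
window centered at frame t covers frames t-4 .. t+3, centers run
``4 .. T-5``, so a T-frame series yields ``T - 8`` windows.  Each 9x8
window is encoded as a 72x72 3-channel 8-bit image: values are mapped by
``floor(v * 255)``, the time axis (rows) is up-sampled x9 and the ROI axis
(columns) x8 by nearest-neighbour block replication, and the grayscale
plane is replicated across the three channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormTraceSet


@dataclass
class WindowStack:
    """Encoded window images plus the raw window tensors they came from."""

    images: np.ndarray  # (n_windows, side, side, 3) uint8
    center_frames: np.ndarray  # (n_windows,) int, relative to dF/F frame 0
    tensors: np.ndarray  # (n_windows, n_rois, window_size) float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.center_frames) > 0):
            raise ValueError("center_frames must be strictly increasing")
        if self.images.shape[0] != len(self.center_frames) != self.tensors.shape[0]:
            raise ValueError("window stack length mismatch")

    @property
    def n_windows(self) -> int:
        return self.images.shape[0]


def make_windows(norm9: NormTraceSet, window_size: int = 8):
    """Slice a (n_rois, T) series into T - window_size windows with centers.

    Returns ``(tensors, centers)`` where ``tensors[i]`` is the
    (n_rois, window_size) slice of frames ``i .. i+window_size-1`` and
    ``centers[i] = i + window_size // 2``.
    """
    v = np.asarray(norm9.values, dtype=float)
    T = v.shape[1]
    n = T - window_size
    if n < 1:
        if n == 0:
            return np.empty((0, v.shape[0], window_size)), np.empty(0, dtype=int)
        raise ValueError(
            f"series too short for windowing: {T} frames, window {window_size}"
        )
    idx = np.arange(n)[:, None] + np.arange(window_size)[None, :]
    tensors = v[:, idx].transpose(1, 0, 2)  # (n, n_rois, window_size)
    centers = np.arange(n) + window_size // 2
    return tensors, centers


def encode_window_image(window: np.ndarray, image_side: int = 72) -> np.ndarray:
    """Encode one (n_rois, window_size) window in [0, 1] as a square uint8 image.

    Rows are time (window_size -> image_side by replication), columns are
    ROIs anterior->posterior left->right (n_rois -> image_side); all three
    channels carry the same values.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be 2-D (n_rois, window_size)")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("window values must lie in [0, 1]")
    n_rois, n_t = w.shape
    if image_side % n_rois != 0 or image_side % n_t != 0:
        raise ValueError(
            f"image_side {image_side} must be divisible by both window axes "
            f"({n_rois} ROIs, {n_t} frames)"
        )
    gray = np.floor(w.T * 255.0).astype(np.uint8)  # (n_t, n_rois), floor keeps 1.0 -> 255
    gray = np.repeat(gray, image_side // n_t, axis=0)
    gray = np.repeat(gray, image_side // n_rois, axis=1)
    return np.repeat(gray[:, :, None], 3, axis=2)


def decode_window_image(image: np.ndarray, n_rois: int = 9, window_size: int = 8) -> np.ndarray:
    """Invert the encoding by block means; exact to within 1/255 per entry."""
    side = image.shape[0]
    gray = np.asarray(image[..., 0], dtype=float) / 255.0
    blocks = gray.reshape(window_size, side // window_size, n_rois, side // n_rois)
    return blocks.mean(axis=(1, 3)).T  # back to (n_rois, window_size)


def encode_stack(tensors: np.ndarray, centers: np.ndarray, image_side: int = 72) -> WindowStack:
    """Encode every window of :func:`make_windows` output into a WindowStack."""
    n = tensors.shape[0]
    images = np.empty((n, image_side, image_side, 3), dtype=np.uint8)
    for i in range(n):
        images[i] = encode_window_image(tensors[i], image_side)
    return WindowStack(images=images, center_frames=np.asarray(centers), tensors=tensors)


def window_stack(norm9: NormTraceSet, window_size: int = 8, image_side: int = 72) -> WindowStack:
    """Convenience: make_windows + encode_stack."""
    tensors, centers = make_windows(norm9, window_size)
    return encode_stack(tensors, centers, image_side)
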