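"""Pooled convolutional features of window images.

The default backbone is the VGG-16 convolutional stack tapped at Conv4_3
(the third convolution of the fourth block).  On a 72x72 input the three
2x2 max-poolings preceding Conv4_3 give a 512-channel 9x9 feature map;
global average pooling over the 81 spatial positions yields one
512-dimensional vector per window.

The forward pass is a direct numpy implementation (3x3 same-padding
convolutions as nine shifted GEMMs, ReLU, 2x2 max-pooling).  Weight sources:

* ``vgg16-random`` - the VGG-16 architecture with seed-deterministic
  He-initialized weights.  Random convolutional features act as a fixed
  nonlinear projection that preserves image similarity, which is all the
  downstream unsupervised clustering needs; nothing has to be downloaded
  and results are bit-reproducible.
* ``vgg16-pretrained`` - identical architecture with weights loaded from a
  user-supplied ``.npz`` file (arrays ``conv{i}_w`` of shape (3, 3, Cin,
  Cout) and ``conv{i}_b``); an error is raised when no file is given.
* ``blockmean`` - a degraded fallback that simply averages the raw image
  over its 9x9 grid of 8x8 blocks (81-dimensional features, no convolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .windowing import WindowStack

# (Cin, Cout) per convolution, "P" = 2x2 max-pool; through conv4_3.
VGG16_CFG = (
    (3, 64), (64, 64), "P",
    (64, 128), (128, 128), "P",
    (128, 256), (256, 256), (256, 256), "P",
    (256, 512), (512, 512), (512, 512),
)

#: Name of each convolution in VGG16_CFG order.
VGG16_LAYER_NAMES = (
    "conv1_1", "conv1_2",
    "conv2_1", "conv2_2",
    "conv3_1", "conv3_2", "conv3_3",
    "conv4_1", "conv4_2", "conv4_3",
)

# Canonical ImageNet channel statistics (RGB, on the 0..1 scale).
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class FeatureMatrix:
    """One pooled feature vector per window."""

    vectors: np.ndarray  # (n_windows, n_features)
    backbone: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite feature values")

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution; x is NHWC float32, w is (3, 3, Cin, Cout)."""
    N, H, W, C = x.shape
    Co = w.shape[3]
    xp = np.zeros((N, H + 2, W + 2, C), dtype=np.float32)
    xp[:, 1:-1, 1:-1, :] = x
    out = np.empty((N, H, W, Co), dtype=np.float32)
    out[...] = b
    tmp = np.empty((N, H, W, Co), dtype=np.float32)
    for dy in range(3):
        for dx in range(3):
            np.matmul(xp[:, dy : dy + H, dx : dx + W, :], w[dy, dx], out=tmp)
            out += tmp
    return out


def _maxpool2(x: np.ndarray) -> np.ndarray:
    N, H, W, C = x.shape
    return x.reshape(N, H // 2, 2, W // 2, 2, C).max(axis=(2, 4))


class FeatureBackbone:
    """Interface: map a uint8 image batch to feature maps (N, C, s, s)."""

    name: str = "backbone"
    input_side: int = 72
    batch_size: int = 32

    def feature_maps(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_contract(self):
        """(channels, spatial_side) declared for ``input_side`` input."""
        raise NotImplementedError


class VGG16Backbone(FeatureBackbone):
    """VGG-16 convolutional stack tapped at a named layer (default conv4_3)."""

    def __init__(
        self,
        weights: list,
        name: str,
        tap_layer: str = "conv4_3",
        normalization: str = "imagenet",
        input_side: int = 72,
    ) -> None:
        if tap_layer not in VGG16_LAYER_NAMES:
            raise ValueError(f"unknown tap layer {tap_layer!r}")
        if normalization not in ("imagenet", "raw"):
            raise ValueError("normalization must be 'imagenet' or 'raw'")
        self.weights = weights
        self.name = name
        self.tap_layer = tap_layer
        self.normalization = normalization
        self.input_side = input_side

    def _preprocess(self, images: np.ndarray) -> np.ndarray:
        x = images.astype(np.float32)
        if self.normalization == "imagenet":
            x = (x / 255.0 - _IMAGENET_MEAN) / _IMAGENET_STD
        return x

    def output_contract(self):
        side = self.input_side
        ci = 0
        for cfg in VGG16_CFG:
            if cfg == "P":
                side //= 2
                continue
            channels = cfg[1]
            if VGG16_LAYER_NAMES[ci] == self.tap_layer:
                return channels, side
            ci += 1
        raise AssertionError("unreachable")

    def feature_maps(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 4 or images.shape[1] != self.input_side or images.shape[3] != 3:
            raise ValueError(
                f"backbone expects (N, {self.input_side}, {self.input_side}, 3) images, "
                f"got {images.shape}"
            )
        outs = []
        for start in range(0, images.shape[0], self.batch_size):
            x = self._preprocess(images[start : start + self.batch_size])
            ci = 0
            for cfg, wb in zip(VGG16_CFG, self.weights):
                if cfg == "P":
                    x = _maxpool2(x)
                    continue
                x = _conv3x3(x, *wb)
                np.maximum(x, 0.0, out=x)
                if VGG16_LAYER_NAMES[ci] == self.tap_layer:
                    break
                ci += 1
            outs.append(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))  # -> NCHW
        return np.concatenate(outs, axis=0)


class BlockMeanBackbone(FeatureBackbone):
    """Pools raw 8x8 image blocks; 81-dimensional features, not CNN-equivalent."""

    name = "blockmean"

    def __init__(self, input_side: int = 72, block: int = 8) -> None:
        if input_side % block != 0:
            raise ValueError("block must divide input_side")
        self.input_side = input_side
        self.block = block

    def output_contract(self):
        return (self.input_side // self.block) ** 2, 1

    def feature_maps(self, images: np.ndarray) -> np.ndarray:
        if images.shape[1] != self.input_side:
            raise ValueError("image side mismatch")
        g = images[..., 0].astype(np.float32) / 255.0
        n = self.input_side // self.block
        blocks = g.reshape(-1, n, self.block, n, self.block).mean(axis=(2, 4))
        return blocks.reshape(-1, n * n, 1, 1)


def _random_vgg_weights(seed: int) -> list:
    rng = np.random.default_rng(seed)
    weights = []
    for cfg in VGG16_CFG:
        if cfg == "P":
            weights.append(None)
            continue
        ci, co = cfg
        std = np.sqrt(2.0 / (9 * ci))  # He initialization for ReLU stacks
        w = rng.standard_normal((3, 3, ci, co)).astype(np.float32) * std
        weights.append((w, np.zeros(co, dtype=np.float32)))
    return weights


def _load_vgg_weights(path) -> list:
    data = np.load(path)
    weights = []
    i = 0
    for cfg in VGG16_CFG:
        if cfg == "P":
            weights.append(None)
            continue
        try:
            w = data[f"conv{i}_w"].astype(np.float32)
            b = data[f"conv{i}_b"].astype(np.float32)
        except KeyError as exc:
            raise ValueError(f"weight file missing arrays for conv {i}") from exc
        if w.shape != (3, 3, cfg[0], cfg[1]):
            raise ValueError(f"conv{i}_w has shape {w.shape}, expected (3, 3, {cfg[0]}, {cfg[1]})")
        weights.append((w, b))
        i += 1
    return weights


def build_backbone(
    kind: str,
    seed: int = 0,
    weights_path=None,
    tap_layer: str = "conv4_3",
    normalization: str = "imagenet",
    input_side: int = 72,
) -> FeatureBackbone:
    """Construct a feature backbone.

    ``kind`` is one of ``vgg16-random`` (seed-deterministic weights),
    ``vgg16-pretrained`` (requires ``weights_path`` to an .npz file) or
    ``blockmean``.
    """
    if kind == "vgg16-random":
        return VGG16Backbone(
            _random_vgg_weights(seed), kind, tap_layer, normalization, input_side
        )
    if kind == "vgg16-pretrained":
        if weights_path is None:
            raise ValueError(
                "vgg16-pretrained requires a weights_path (.npz); "
                "use vgg16-random for a download-free run"
            )
        return VGG16Backbone(
            _load_vgg_weights(weights_path), kind, tap_layer, normalization, input_side
        )
    if kind == "blockmean":
        return BlockMeanBackbone(input_side)
    raise ValueError(f"unknown backbone kind {kind!r}")


def global_average_pool(feature_maps: np.ndarray) -> np.ndarray:
    """Mean over the spatial positions of each channel: (N, C, s, s) -> (N, C)."""
    return feature_maps.mean(axis=(2, 3))


def extract_features(stack: WindowStack, backbone: FeatureBackbone) -> FeatureMatrix:
    """Forward every window image through the backbone and pool spatially."""
    if stack.n_windows == 0:
        c, _ = backbone.output_contract()
        return FeatureMatrix(np.empty((0, c)), backbone.name)
    maps = backbone.feature_maps(stack.images)
    return FeatureMatrix(global_average_pool(maps).astype(np.float64), backbone.name)
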