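"""Image preprocessing, batch normalization, and the convolutional feature stack.

The extractor mirrors the AlexNet convolutional geometry: a 227x227x3
input run through five convolutions (each followed by batch normalization
and ReLU) interleaved with three 3x3/stride-2 max pools, flattened to a
9216-vector (6 x 6 x 256) that feeds the ELM classifier head.

No filters are trained here.  Default filters are seeded random tensors
with unit-norm rows, i.e. the stack acts as a structured random
projection; externally supplied filter tensors can be plugged in instead.
Batch normalization at inference standardizes each channel map with its
own per-image statistics (there is no training loop to accumulate running
averages from).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "IMAGE_SIZE",
    "FEATURE_LENGTH",
    "BatchNormParams",
    "ConvStackConfig",
    "ConvFeatureExtractor",
    "batch_statistics",
    "batch_normalize",
    "preprocess_image",
    "load_dicom_pixels",
    "extract_feature_matrix",
    "default_alexnet_stack",
]

IMAGE_SIZE = 227
FEATURE_LENGTH = 9216  # 6 * 6 * 256


@dataclass(frozen=True)
class BatchNormParams:
    """Affine batch-norm transform y = shift + scale * z_hat."""

    scale: float = 1.0   # b, multiplies the standardized value
    shift: float = 0.0   # a, additive offset
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def batch_statistics(values: np.ndarray) -> Tuple[float, float]:
    """Mini-batch mean and biased variance (1/N divisor)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot compute statistics of an empty batch")
    mean = float(np.mean(v))
    var = float(np.mean((v - mean) ** 2))
    return mean, var


def batch_normalize(
    values: np.ndarray, params: BatchNormParams = BatchNormParams()
) -> np.ndarray:
    """Standardize with batch statistics, then apply the affine transform."""
    v = np.asarray(values, dtype=float)
    mean, var = batch_statistics(v)
    z_hat = (v - mean) / np.sqrt(var + params.epsilon)
    return params.shift + params.scale * z_hat


def preprocess_image(path: Union[str, Path]) -> np.ndarray:
    """Load a PNG/JPEG, resize to 227x227 bilinear, return HxWx3 in [0,1].

    Grayscale images are replicated across the three channels.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize(
                (IMAGE_SIZE, IMAGE_SIZE), Image.Resampling.BILINEAR
            )
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, ValueError) as exc:
        raise ValueError(f"could not read image {path}: {exc}") from exc
    return arr


def load_dicom_pixels(path: Union[str, Path]) -> np.ndarray:
    """Optional DICOM reader (pixel data only); rescales to [0,1] HxWx3."""
    import pydicom  # feature-flagged dependency

    ds = pydicom.dcmread(str(path))
    px = ds.pixel_array.astype(np.float64)
    lo, hi = px.min(), px.max()
    px = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    im = Image.fromarray((px * 255).astype(np.uint8)).convert("RGB")
    im = im.resize((IMAGE_SIZE, IMAGE_SIZE), Image.Resampling.BILINEAR)
    return np.asarray(im, dtype=np.float64) / 255.0


# ---------------------------------------------------------------------------
# convolutional stack


@dataclass(frozen=True)
class ConvLayer:
    filters: int
    kernel: int
    stride: int = 1
    padding: int = 0
    batch_norm: bool = True


@dataclass(frozen=True)
class PoolLayer:
    kernel: int = 3
    stride: int = 2


LayerSpec = Union[ConvLayer, PoolLayer]


def default_alexnet_stack() -> Tuple[LayerSpec, ...]:
    """The five-conv / three-pool sequence ending at 6x6x256 = 9216."""
    return (
        ConvLayer(filters=96, kernel=11, stride=4, padding=0),
        PoolLayer(),
        ConvLayer(filters=256, kernel=5, stride=1, padding=2),
        PoolLayer(),
        ConvLayer(filters=384, kernel=3, stride=1, padding=1),
        ConvLayer(filters=384, kernel=3, stride=1, padding=1),
        ConvLayer(filters=256, kernel=3, stride=1, padding=1),
        PoolLayer(),
    )


@dataclass(frozen=True)
class ConvStackConfig:
    layers: Tuple[LayerSpec, ...] = field(default_factory=default_alexnet_stack)
    input_size: int = IMAGE_SIZE
    input_channels: int = 3

    def shape_chain(self) -> list[Tuple[int, int, int]]:
        """(H, W, C) after each layer; raises at construction-time misuse."""
        h = w = self.input_size
        c = self.input_channels
        chain = []
        for layer in self.layers:
            if isinstance(layer, ConvLayer):
                span = h - layer.kernel + 2 * layer.padding
                pad = layer.padding
            else:
                span = h - layer.kernel
                pad = 0
            if span < 0 or span % layer.stride != 0:
                raise ValueError(
                    f"layer {layer} does not tile a {h}x{w} input exactly"
                )
            h = (h - layer.kernel + 2 * pad) // layer.stride + 1
            w = (w - layer.kernel + 2 * pad) // layer.stride + 1
            if isinstance(layer, ConvLayer):
                c = layer.filters
            if h < 1 or w < 1:
                raise ValueError("layer chain collapses below 1x1")
            chain.append((h, w, c))
        return chain

    @property
    def output_length(self) -> int:
        h, w, c = self.shape_chain()[-1]
        return h * w * c


def _conv2d(x: np.ndarray, filters: np.ndarray, stride: int, padding: int) -> np.ndarray:
    """Valid cross-correlation via im2col; x is HxWxC, filters (K, kh, kw, C)."""
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    kh, kw = filters.shape[1], filters.shape[2]
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
    windows = windows[::stride, ::stride]            # (H', W', C, kh, kw)
    hp, wp = windows.shape[0], windows.shape[1]
    cols = windows.transpose(0, 1, 3, 4, 2).reshape(hp * wp, kh * kw * x.shape[2])
    fmat = filters.transpose(0, 1, 2, 3).reshape(filters.shape[0], -1)  # (K, kh*kw*C)
    out = cols @ fmat.T
    return out.reshape(hp, wp, filters.shape[0])


def _maxpool(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(0, 1))
    windows = windows[::stride, ::stride]
    return windows.max(axis=(3, 4))


def _bn_relu(x: np.ndarray, params: BatchNormParams) -> np.ndarray:
    """Per-channel batch normalization (this map's statistics) then ReLU."""
    mean = x.mean(axis=(0, 1), keepdims=True)
    var = x.var(axis=(0, 1), keepdims=True)
    z = (x - mean) / np.sqrt(var + params.epsilon)
    return np.maximum(params.shift + params.scale * z, 0.0)


class ConvFeatureExtractor:
    """Seeded random-filter convolutional stack producing 9216-vectors.

    Filters default to unit-norm random tensors drawn from the given seed;
    a list of externally supplied filter tensors (one ``(K, kh, kw, C_in)``
    array per conv layer) can replace them via ``filters``.
    """

    def __init__(
        self,
        config: Optional[ConvStackConfig] = None,
        seed: int = 0,
        filters: Optional[Sequence[np.ndarray]] = None,
        bn_params: BatchNormParams = BatchNormParams(),
    ) -> None:
        self.config = config or ConvStackConfig()
        self.bn_params = bn_params
        chain = self.config.shape_chain()  # validates geometry eagerly
        self._chain = chain

        conv_layers = [l for l in self.config.layers if isinstance(l, ConvLayer)]
        if filters is not None:
            if len(filters) != len(conv_layers):
                raise ValueError(
                    f"expected {len(conv_layers)} filter tensors, got {len(filters)}"
                )
            self.filters = [np.asarray(f, dtype=np.float32) for f in filters]
            self._check_filter_shapes(conv_layers)
        else:
            self.filters = self._random_filters(conv_layers, seed)

    def _check_filter_shapes(self, conv_layers: Sequence[ConvLayer]) -> None:
        c_in = self.config.input_channels
        for f, layer in zip(self.filters, conv_layers):
            expect = (layer.filters, layer.kernel, layer.kernel, c_in)
            if f.shape != expect:
                raise ValueError(f"filter tensor shape {f.shape} != expected {expect}")
            c_in = layer.filters

    def _random_filters(
        self, conv_layers: Sequence[ConvLayer], seed: int
    ) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        out = []
        c_in = self.config.input_channels
        for layer in conv_layers:
            f = rng.standard_normal(
                (layer.filters, layer.kernel, layer.kernel, c_in)
            ).astype(np.float32)
            flat = f.reshape(layer.filters, -1)
            flat /= np.linalg.norm(flat, axis=1, keepdims=True)
            out.append(flat.reshape(f.shape))
            c_in = layer.filters
        return out

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Run the stack on a 227x227x3 tensor; returns the 9216-vector."""
        x = np.asarray(image, dtype=np.float32)
        expect = (self.config.input_size, self.config.input_size, self.config.input_channels)
        if x.shape != expect:
            raise ValueError(f"image must have shape {expect}, got {x.shape}")
        fi = 0
        for layer in self.config.layers:
            if isinstance(layer, ConvLayer):
                x = _conv2d(x, self.filters[fi], layer.stride, layer.padding)
                fi += 1
                if layer.batch_norm:
                    x = _bn_relu(x, self.bn_params)
                else:
                    x = np.maximum(x, 0.0)
            else:
                x = _maxpool(x, layer.kernel, layer.stride)
        return x.astype(np.float64).ravel()


def extract_feature_matrix(
    manifest: pd.DataFrame,
    extractor: Optional[ConvFeatureExtractor] = None,
    image_root: Optional[Union[str, Path]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Features + labels for every (filepath, label) row of a manifest."""
    if extractor is None:
        extractor = ConvFeatureExtractor()
    root = Path(image_root) if image_root is not None else None
    feats = np.empty((len(manifest), extractor.config.output_length))
    labels = np.empty(len(manifest), dtype=int)
    for i, row in enumerate(manifest.itertuples(index=False)):
        p = Path(row.filepath)
        if root is not None and not p.is_absolute():
            p = root / p
        feats[i] = extractor.extract(preprocess_image(p))
        labels[i] = int(row.label)
    return feats, labels
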