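"""Feature extraction: images -> fixed-length activation vectors.

The benchmark treats a vision model as a black-box map f from an image to
an ordered numeric vector (a layer's activations, flattened row-major over
channel, height, width).  The built-in :class:`ToyExtractor` — a seeded
random linear map of the block-averaged pixel grid, optionally rectified —
makes every downstream stage testable offline and deterministically.

Adapters for the nine pretrained ImageNet CNNs live in
:mod:`closurebench.cnn_adapters` (optional ``cnn`` extra); the model/layer
registry below is static so result manifests are well-defined even when
that extra is not installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np

# model id -> extraction layer, one entry per benchmarked architecture.
# AlexNet's "last fully-connected layer" is taken as the final 1000-unit
# layer before the softmax (overridable in the adapter).
LAYER_REGISTRY = {
    "vgg16": "last convolutional layer (features.28)",
    "squeezenet_v1_1": "last convolutional layer (classifier.1)",
    "shufflenet_v2": "last convolutional layer (conv5)",
    "mobilenet_v3": "last convolutional layer (features.16)",
    "efficientnet_b0": "final MBConv6 block (features.8)",
    "inception_v3": "Mixed_7c",
    "alexnet": "last fully-connected layer (classifier.6, 1000-d, pre-softmax)",
    "resnet50": "final average pooling layer (avgpool)",
    "densenet121": "final dense block (features.denseblock4)",
}


class ExtractionError(RuntimeError):
    pass


def _as_array(image) -> np.ndarray:
    if hasattr(image, "pixels"):
        image = image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return arr


def _block_mean(arr: np.ndarray, d: int) -> np.ndarray:
    """Average the image over a d x d grid of (near-)equal rectangular blocks."""
    h, w = arr.shape
    if h % d == 0 and w % d == 0:
        return arr.reshape(d, h // d, d, w // d).mean(axis=(1, 3))
    ri = (np.arange(d + 1) * h) // d
    ci = (np.arange(d + 1) * w) // d
    out = np.empty((d, d), dtype=np.float64)
    for i in range(d):
        for j in range(d):
            out[i, j] = arr[ri[i]:ri[i + 1], ci[j]:ci[j + 1]].mean()
    return out


@dataclass(frozen=True)
class ToyExtractor:
    """Seeded random projection of the downsampled pixel grid.

    The image is block-averaged to ``downsample`` x ``downsample`` (the
    default 60 gives 5-px blocks, fine enough to resolve every stimulus
    difference in the benchmark grids, including the smallest inducers), scaled
    to [0, 1], flattened row-major, and multiplied by a fixed Gaussian
    matrix drawn once from ``seed``.  With ``nonlinear=False`` the map is
    exactly linear in the pixel values (no bias), so it preserves the
    raster-level null of the configural-effect design; ``nonlinear=True``
    adds a fixed bias and a rectification, breaking that null the way a
    real network's layers do.
    """

    seed: int
    output_dim: int = 64
    downsample: int = 60
    nonlinear: bool = False

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    @property
    def id(self) -> str:
        kind = "relu" if self.nonlinear else "linear"
        return f"toy-{kind}-s{self.seed}-d{self.output_dim}-g{self.downsample}"

    @lru_cache(maxsize=None)
    def _weights(self):
        rng = np.random.default_rng(self.seed)
        n_in = self.downsample * self.downsample
        w = rng.standard_normal((self.output_dim, n_in)) / np.sqrt(n_in)
        b = rng.standard_normal(self.output_dim) * 0.1
        return w, b

    def extract(self, image) -> np.ndarray:
        arr = _as_array(image) / 255.0
        x = _block_mean(arr, self.downsample).ravel()
        w, b = self._weights()
        v = w @ x
        if self.nonlinear:
            v = np.maximum(v + b, 0.0)
        if not np.all(np.isfinite(v)):
            raise ExtractionError(f"non-finite activations from extractor {self.id}")
        return v


def make_toy_extractor(seed: int, output_dim: int = 64, downsample: int = 60,
                       nonlinear: bool = False) -> ToyExtractor:
    return ToyExtractor(seed=seed, output_dim=output_dim,
                        downsample=downsample, nonlinear=nonlinear)


def extract(image, extractor) -> np.ndarray:
    """Apply any extractor (an object with ``.extract``) to one image."""
    v = np.asarray(extractor.extract(image), dtype=np.float64)
    if not np.all(np.isfinite(v)):
        name = getattr(extractor, "id", type(extractor).__name__)
        raise ExtractionError(f"non-finite activations from extractor {name}")
    return v


def get_extractor(name: str, seed: int = 0,
                  **kwargs) -> Union[ToyExtractor, object]:
    """Resolve an extractor by name: 'toy', 'toy-relu', or a registry model id."""
    if name == "toy":
        return make_toy_extractor(seed, **kwargs)
    if name == "toy-relu":
        return make_toy_extractor(seed, nonlinear=True, **kwargs)
    if name in LAYER_REGISTRY:
        from .cnn_adapters import make_cnn_extractor
        return make_cnn_extractor(name, **kwargs)
    raise ValueError(
        f"unknown extractor {name!r}; expected 'toy', 'toy-relu', "
        f"or one of {sorted(LAYER_REGISTRY)}"
    )
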