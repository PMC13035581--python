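"""Optional adapters exposing pretrained ImageNet CNNs as extractors.

Requires the ``cnn`` extra (torch + torchvision) and, on first use, a
download of pretrained weights.  The core package and its test suite never
import torch; these adapters exist for qualitative replication runs on the
real models at the layers named in :data:`closurebench.features.LAYER_REGISTRY`.

Preprocessing: the 300x300 grayscale stimulus is resized to the model's
canonical input size, replicated to three channels, and normalized with
the standard ImageNet statistics.  Multi-dimensional layer outputs are
flattened row-major over (channel, height, width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import LAYER_REGISTRY, ExtractionError

# torchvision constructor, hook target module path, input size
_MODEL_TABLE = {
    "vgg16": ("vgg16", "features.28", 224),
    "squeezenet_v1_1": ("squeezenet1_1", "features.12", 224),
    "shufflenet_v2": ("shufflenet_v2_x1_0", "conv5", 224),
    "mobilenet_v3": ("mobilenet_v3_large", "features.16", 224),
    "efficientnet_b0": ("efficientnet_b0", "features.8", 224),
    "inception_v3": ("inception_v3", "Mixed_7c", 299),
    "alexnet": ("alexnet", "classifier.6", 224),
    "resnet50": ("resnet50", "avgpool", 224),
    "densenet121": ("densenet121", "features.denseblock4", 224),
}

_IMAGENET_MEAN = (0.485, 0.456, 0.406)
_IMAGENET_STD = (0.229, 0.224, 0.225)


def _require_torch():
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - exercised without torch
        raise ImportError(
            "pretrained CNN adapters require the 'cnn' extra "
            "(pip install closurebench[cnn]); the built-in toy extractor "
            "needs no extra dependencies"
        ) from exc
    return torch, torchvision


@dataclass
class CNNExtractor:
    """Forward-hook extractor at the registry layer of one pretrained model."""

    model_id: str
    layer_override: str | None = None
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def id(self) -> str:
        return f"{self.model_id}:{self.layer_override or _MODEL_TABLE[self.model_id][1]}"

    @property
    def layer_description(self) -> str:
        return LAYER_REGISTRY[self.model_id]

    def _setup(self):
        torch, torchvision = _require_torch()
        ctor_name, layer_path, size = _MODEL_TABLE[self.model_id]
        model = getattr(torchvision.models, ctor_name)(weights="DEFAULT")
        model.eval()
        target = model
        for part in (self.layer_override or layer_path).split("."):
            target = target[int(part)] if part.isdigit() else getattr(target, part)
        captured = {}
        target.register_forward_hook(
            lambda m, i, o: captured.__setitem__("out", o.detach()))
        self._state.update(torch=torch, model=model, size=size, captured=captured)

    def extract(self, image) -> np.ndarray:
        if not self._state:
            self._setup()
        torch = self._state["torch"]
        arr = np.asarray(getattr(image, "pixels", image), dtype=np.float32) / 255.0
        t = torch.from_numpy(arr)[None, None]
        t = torch.nn.functional.interpolate(
            t, size=self._state["size"], mode="bilinear", align_corners=False)
        t = t.repeat(1, 3, 1, 1)
        mean = torch.tensor(_IMAGENET_MEAN).view(1, 3, 1, 1)
        std = torch.tensor(_IMAGENET_STD).view(1, 3, 1, 1)
        with torch.no_grad():
            self._state["model"]((t - mean) / std)
        out = self._state["captured"]["out"].reshape(-1).numpy().astype(np.float64)
        if not np.all(np.isfinite(out)):
            raise ExtractionError(f"non-finite activations from extractor {self.id}")
        return out


def make_cnn_extractor(model_id: str, layer: str | None = None) -> CNNExtractor:
    if model_id not in _MODEL_TABLE:
        raise ValueError(f"unknown model {model_id!r}")
    _require_torch()
    return CNNExtractor(model_id, layer_override=layer)
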