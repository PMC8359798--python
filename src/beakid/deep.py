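"""Deep-feature extraction through pluggable backbone adapters.

Three backbone geometries are supported, matching the transfer-learning
conventions of the original architectures:

=============  ==========  ===========  ================================
name           input size  feature dim  tap point
=============  ==========  ===========  ================================
vgg19          224x224     4096         second fully connected layer
inceptionv3    299x299     2048         global average pool
resnet50       224x224     2048         global average pool
=============  ==========  ===========  ================================

Preprocessing is shared: bilinear resize to the square input size followed
by per-channel mean-RGB subtraction (the conventional ImageNet channel
means, stored below as literals).

Two weight modes exist.  ``random`` instantiates a seeded random-feature
adapter — a fixed random projection with a rectified-linear nonlinearity
from the preprocessed input to the backbone's feature dimension.  It is
deterministic given its seed, reproduces every architecture's input/output
geometry, and needs no weight files; it carries no learned semantics, so it
exercises shapes, determinism and plumbing rather than accuracy.
``pretrained`` requires a torch + torchvision installation with downloaded
weights and raises :class:`BackboneUnavailableError` when absent.
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import BackboneUnavailableError, InvalidParameterError
from .imaging import load_rgb

#: (input edge px, feature dimension) per backbone.
BACKBONE_TABLE = {
    "vgg19": (224, 4096),
    "inceptionv3": (299, 2048),
    "resnet50": (224, 2048),
}

#: Conventional ImageNet channel means (R, G, B) used for mean subtraction.
MEAN_RGB = (123.68, 116.779, 103.939)


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    weights: str = "random"  # {"pretrained", "random"}

    def __post_init__(self):
        if self.name not in BACKBONE_TABLE:
            raise InvalidParameterError(
                f"unknown backbone {self.name!r}; choose from {sorted(BACKBONE_TABLE)}"
            )
        if self.weights not in ("pretrained", "random"):
            raise InvalidParameterError("weights must be 'pretrained' or 'random'")

    @property
    def input_size(self) -> int:
        return BACKBONE_TABLE[self.name][0]

    @property
    def feature_dim(self) -> int:
        return BACKBONE_TABLE[self.name][1]


def backbone_preprocess(img: np.ndarray, spec: BackboneSpec) -> np.ndarray:
    """Resize to the backbone's square input and subtract the channel means.

    Returns a float (size, size, 3) array in RGB channel order.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError(f"expected an (H, W, 3) image, got shape {img.shape}")
    s = spec.input_size
    out = _sk_resize(img, (s, s), order=1, anti_aliasing=False, preserve_range=True)
    return out - np.asarray(MEAN_RGB)


class RandomFeatureAdapter:
    """Seeded random-feature map with a backbone's input/output geometry.

    The preprocessed input is average-pooled to a 32x32x3 patch grid,
    flattened, and passed through a fixed Gaussian random projection with a
    rectified-linear nonlinearity.  Weights are drawn once from the seed at
    construction, so extraction is deterministic and repeatable.
    """

    _POOLED = 32

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_in = self._POOLED * self._POOLED * 3
        scale = np.sqrt(2.0 / n_in)
        self.weight = rng.normal(0.0, scale, size=(n_in, spec.feature_dim)).astype(np.float32)
        self.bias = rng.normal(0.0, 0.01, size=spec.feature_dim).astype(np.float32)

    def features(self, prepared: np.ndarray) -> np.ndarray:
        s = self.spec.input_size
        if prepared.shape != (s, s, 3):
            raise InvalidParameterError(
                f"{self.spec.name} expects input {(s, s, 3)}, got {prepared.shape}"
            )
        pooled = _sk_resize(
            np.asarray(prepared, dtype=float),
            (self._POOLED, self._POOLED),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        x = (pooled.reshape(-1) / 255.0).astype(np.float32)
        return np.maximum(x @ self.weight + self.bias, 0.0).astype(np.float64)


def build_adapter(spec: BackboneSpec, seed: int = 0):
    """Instantiate the adapter for ``spec``.

    ``random`` weights always succeed offline; ``pretrained`` needs torch +
    torchvision and raises :class:`BackboneUnavailableError` otherwise.
    """
    if spec.weights == "random":
        return RandomFeatureAdapter(spec, seed)
    if importlib.util.find_spec("torchvision") is None:
        raise BackboneUnavailableError(
            f"backbone unavailable: pretrained {spec.name} weights require torchvision"
        )
    from ._torch_adapters import TorchBackboneAdapter  # pragma: no cover

    return TorchBackboneAdapter(spec)  # pragma: no cover


def extract_deep_features(
    manifest: pd.DataFrame,
    spec: BackboneSpec,
    root: str | Path = ".",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """One feature row per manifest record, in manifest order.

    Returns ``(table, errors)``: the table has columns
    ``{name}_0 .. {name}_{dim-1}`` plus a final ``label`` column; records
    whose image file cannot be read are collected in ``errors`` as
    ``(path, message)`` and skipped, the run continues.
    """
    adapter = build_adapter(spec, seed)
    root = Path(root)
    rows, labels, errors = [], [], []
    for rec in manifest.itertuples(index=False):
        try:
            img = load_rgb(root / rec.path)
        except OSError as exc:
            errors.append((str(rec.path), str(exc)))
            continue
        rows.append(adapter.features(backbone_preprocess(img, spec)))
        labels.append(rec.label)
    cols = [f"{spec.name}_{i}" for i in range(spec.feature_dim)]
    table = pd.DataFrame(rows, columns=cols)
    table["label"] = labels
    return table, errors
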