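"""Deep-feature extraction interface.

An image goes in, a fixed-length real vector comes out. Real
convolutional backbones (VGG16/19, ResNet50, InceptionV3, Xception) are
optional plug-ins that require a deep-learning framework and pretrained
weights; the built-in ``mock`` backbone — a fixed random projection of
pooled patch statistics — is deterministic, weight-free, and preserves
the coarse contrast structure (e.g. dark pest blobs) that downstream
selection and classification rely on, so the whole pipeline is testable
offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .selection import FeatureMatrix

INPUT_SIZE = (224, 224, 3)

# published penultimate-layer widths of the real backbones
REAL_BACKBONE_DIMS = {
    "vgg16": 4096,
    "vgg19": 4096,
    "resnet50": 2048,
    "inceptionv3": 2048,
    "xception": 2048,
}


@dataclass
class BackboneSpec:
    """Which feature extractor to use.

    ``output_dim`` is configurable for the mock backbone only; real
    backbones have it fixed by their published architecture.
    """

    name: str = "mock"
    output_dim: int = 256
    mock_seed: int = 12345
    patch_grid: int = 8

    def __post_init__(self) -> None:
        if self.name not in ("mock", *REAL_BACKBONE_DIMS):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.name != "mock":
            self.output_dim = REAL_BACKBONE_DIMS[self.name]
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


def _prepare(img: np.ndarray) -> np.ndarray:
    """Resize to 224 x 224 x 3, scale to [0, 1] and standardize each
    channel (the mock's input normalization, mirroring the published
    per-backbone preprocessing of the real plug-ins)."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[-1] == 1:
        img = np.repeat(img, 3, axis=2)
    out = resize(img / 255.0, INPUT_SIZE, order=1, mode="reflect",
                 anti_aliasing=True)
    mean = out.mean(axis=(0, 1), keepdims=True)
    sd = out.std(axis=(0, 1), keepdims=True)
    return (out - mean) / np.maximum(sd, 1e-8)


def _patch_statistics(img: np.ndarray, grid: int) -> np.ndarray:
    """Per-patch mean, standard deviation and dark extreme (5th
    percentile) over a grid x grid tiling, per channel — the pooled
    summary the mock projects. The dark extreme keeps localized
    low-intensity structure (pest bodies) visible after projection."""
    h, w, c = img.shape
    stats = []
    ys = np.linspace(0, h, grid + 1, dtype=int)
    xs = np.linspace(0, w, grid + 1, dtype=int)
    for i in range(grid):
        for j in range(grid):
            patch = img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            stats.append(patch.mean(axis=(0, 1)))
            stats.append(patch.std(axis=(0, 1)))
            stats.append(np.quantile(patch.reshape(-1, c), 0.05, axis=0))
    return np.concatenate(stats)


def _mock_projection(spec: BackboneSpec, stat_dim: int) -> np.ndarray:
    """The mock's fixed weights: seeded by the backbone's internal seed
    only, never by the images."""
    rng = np.random.default_rng(spec.mock_seed)
    return rng.standard_normal((stat_dim, spec.output_dim)) / np.sqrt(stat_dim)


def extract_features(images: list, spec: BackboneSpec) -> FeatureMatrix:
    """Turn a batch of images into an n x output_dim feature table.

    Rows follow input order. Extraction is a pure function of the pixel
    content and the backbone spec; batch composition does not matter.
    """
    if spec.name != "mock":
        raise ImportError(
            f"backbone {spec.name!r} needs a deep-learning framework with "
            f"pretrained weights; install the 'torchvision' extra or use "
            f"the 'mock' backbone"
        )
    rows = []
    projection = None
    for img in images:
        stats = _patch_statistics(_prepare(img), spec.patch_grid)
        if projection is None:
            projection = _mock_projection(spec, stats.size)
        rows.append(np.tanh(stats @ projection))
    if not rows:
        raise ValueError("no images supplied")
    values = np.vstack(rows)
    names = [f"{spec.name}_{j}" for j in range(spec.output_dim)]
    return FeatureMatrix(values=values, feature_names=names)
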