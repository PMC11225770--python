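"""Seeded generators for feature tables, toy pest images and optimizer
benchmarks.

These emulate the study conditions — two-class deep-feature tables with
a known informative subset, and pest / no-pest image pairs — so every
stage of the pipeline is testable without the real image collection or
pretrained network weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SyntheticSpec:
    """Parameters of a generated two-class Gaussian feature table.

    ``separation`` is the class-mean gap on each informative dimension,
    in units of the noise standard deviation.
    """

    n_per_class: int = 200
    d: int = 50
    n_informative: int = 10
    separation: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.d:
            raise ValueError("n_informative must be <= d")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_feature_table(spec: SyntheticSpec):
    """Two-class Gaussian table with a known informative subset.

    Class 0 is Normal(0, sd) everywhere; class 1 has mean
    separation * sd on the informative dimensions and 0 elsewhere.

    Returns ``(X, y, informative)`` — the n x d matrix, the 0/1 label
    vector and the sorted array of informative column indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    informative = np.sort(rng.choice(spec.d, size=spec.n_informative, replace=False))
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
    y = np.repeat([0, 1], spec.n_per_class)
    X[spec.n_per_class:, informative] += spec.separation * spec.noise_sd
    perm = rng.permutation(n)
    return X[perm], y[perm], informative


def generate_toy_images(n_per_class: int, size: int = 64, seed: int = 0):
    """Toy pest / no-pest image pairs.

    "Pest" images carry 1-3 dark elliptical blobs with jittered pose on
    a bright textured background; "no-pest" images are background only.

    Returns ``(images, labels)`` with uint8 H x W x 3 arrays and labels
    0 (no pest) / 1 (pest).
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    yy, xx = np.mgrid[0:size, 0:size]
    for label in (0, 1):
        for _ in range(n_per_class):
            base = rng.uniform(150.0, 200.0)
            img = base + rng.normal(0.0, 12.0, size=(size, size))
            # gentle illumination gradient, as in field photographs
            img += rng.uniform(-0.3, 0.3) * (xx - size / 2)
            if label == 1:
                for _ in range(int(rng.integers(1, 4))):
                    cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
                    ry = rng.uniform(0.06 * size, 0.12 * size)
                    rx = rng.uniform(0.06 * size, 0.12 * size)
                    phi = rng.uniform(0.0, np.pi)
                    dy, dx = yy - cy, xx - cx
                    u = dy * np.cos(phi) + dx * np.sin(phi)
                    v = -dy * np.sin(phi) + dx * np.cos(phi)
                    blob = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
                    img[blob] = rng.uniform(20.0, 60.0)
            img = np.clip(img, 0.0, 255.0).astype(np.uint8)
            images.append(np.repeat(img[:, :, None], 3, axis=2))
            labels.append(label)
    return images, np.asarray(labels)


_BENCHMARKS = {}


def _register(name, lower, upper):
    def deco(fn):
        _BENCHMARKS[name] = (fn, lower, upper)
        return fn

    return deco


@_register("sphere", -5.12, 5.12)
def _sphere(x):
    return float(np.sum(x * x))


@_register("rastrigin", -5.12, 5.12)
def _rastrigin(x):
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


@_register("rosenbrock", -2.048, 2.048)
def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def random_search_baseline(objective, lower, upper, n_evaluations: int,
                           seed: int = 0) -> float:
    """Best objective value over a fixed budget of uniform draws — the
    equal-budget baseline population-based optimizers must beat."""
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_evaluations):
        value = objective(rng.uniform(lower, upper))
        if value < best:
            best = value
    return best


def benchmark_function(name: str, dim: int):
    """Standard test objective with its known optimum and default box.

    Returns ``(objective, optimum_position, optimum_value, lower, upper)``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    try:
        fn, lo, hi = _BENCHMARKS[name]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARKS)}"
        ) from None
    optimum = np.ones(dim) if name == "rosenbrock" else np.zeros(dim)
    return fn, optimum, 0.0, np.full(dim, lo), np.full(dim, hi)
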