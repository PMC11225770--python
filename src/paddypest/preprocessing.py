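"""Image filtering and augmentation.

Filters (Gaussian, average, median) smooth field photographs before
feature extraction; the seven augmentation operators artificially
expand a small image collection. Images are H x W or H x W x C arrays
of intensities in [0, 255]; every operator preserves shape and range
and uses reflective border handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.ndimage as ndi


def kernel_size_schedule(A: int) -> int:
    """Odd kernel size a = 2A - 1 for schedule index A = 1, 2, 3, ..."""
    if A < 1:
        raise ValueError("A must be >= 1")
    return 2 * A - 1


@dataclass
class FilterSpec:
    kind: str  # gaussian | average | median
    kernel_size: int = 3
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "average", "median"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("image must be H x W or H x W x C")
    return img


def _finish(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, 255.0)


def _per_channel(img: np.ndarray, fn) -> np.ndarray:
    if img.ndim == 2:
        return fn(img)
    return np.stack([fn(img[..., c]) for c in range(img.shape[-1])], axis=-1)


def gaussian_kernel_1d(kernel_size: int, sigma: float) -> np.ndarray:
    """G(x) = 1/(2 pi sigma^2) exp(-x^2 / (2 sigma^2)) sampled on integer
    offsets and renormalized to sum 1."""
    half = kernel_size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)
    return g / g.sum()


def gaussian_filter(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Separable Gaussian blur with the sampled, renormalized kernel."""
    if spec.sigma <= 0:
        raise ValueError("sigma must be > 0")
    img = _as_float(img)
    kernel = gaussian_kernel_1d(spec.kernel_size, spec.sigma)

    def blur(channel):
        out = ndi.convolve1d(channel, kernel, axis=0, mode="reflect")
        return ndi.convolve1d(out, kernel, axis=1, mode="reflect")

    return _finish(_per_channel(img, blur))


def average_filter(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Each pixel replaced by the mean of its a x a window."""
    img = _as_float(img)
    a = spec.kernel_size
    return _finish(
        _per_channel(img, lambda c: ndi.uniform_filter(c, size=a, mode="reflect"))
    )


def median_filter(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Each pixel replaced by the median of its a x a window."""
    img = _as_float(img)
    a = spec.kernel_size
    return _finish(
        _per_channel(img, lambda c: ndi.median_filter(c, size=a, mode="reflect"))
    )


def apply_filter(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    return {"gaussian": gaussian_filter,
            "average": average_filter,
            "median": median_filter}[spec.kind](img, spec)


# ---------------------------------------------------------------------
# augmentation

AUGMENT_OPERATIONS = (
    "horizontal_flip",
    "vertical_flip",
    "rotation",
    "shear",
    "contrast_increase",
    "reflection",
    "brightness",
)


@dataclass
class AugmentSpec:
    """The seven expansion operators.

    Contrast is fixed at a 20 % increase (factor 1.2). Rotation angle,
    shear factor and brightness delta default to 15 degrees, 0.1 and
    +25. "Reflection" is a vertical-axis mirror and therefore duplicates
    ``horizontal_flip``; both are kept so the operator count matches the
    seven-step expansion.
    """

    operations: tuple = AUGMENT_OPERATIONS
    rotation_angle: float = 15.0
    shear_factor: float = 0.1
    contrast_factor: float = 1.2
    brightness_delta: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.operations) - set(AUGMENT_OPERATIONS)
        if unknown:
            raise ValueError(f"unknown augmentation operations: {sorted(unknown)}")


def _rotate(img, angle):
    def rot(channel):
        return ndi.rotate(channel, angle, reshape=False, order=1, mode="reflect")

    return _per_channel(img, rot)


def _shear(img, factor):
    matrix = np.array([[1.0, factor], [0.0, 1.0]])
    center = (np.array(img.shape[:2]) - 1) / 2.0
    offset = center - matrix @ center

    def shear(channel):
        return ndi.affine_transform(channel, matrix, offset=offset, order=1,
                                    mode="reflect")

    return _per_channel(img, shear)


def _contrast(img, factor):
    if img.ndim == 2:
        mean = img.mean()
    else:
        mean = img.mean(axis=(0, 1), keepdims=True)
    return mean + factor * (img - mean)


def augment(img: np.ndarray, spec: AugmentSpec) -> list[np.ndarray]:
    """One output image per requested operation, in request order."""
    img = _as_float(img)
    outputs = []
    for op in spec.operations:
        if op == "horizontal_flip" or op == "reflection":
            out = img[:, ::-1].copy()
        elif op == "vertical_flip":
            out = img[::-1].copy()
        elif op == "rotation":
            out = _rotate(img, spec.rotation_angle)
        elif op == "shear":
            out = _shear(img, spec.shear_factor)
        elif op == "contrast_increase":
            out = _contrast(img, spec.contrast_factor)
        elif op == "brightness":
            out = img + spec.brightness_delta
        else:  # pragma: no cover - guarded by AugmentSpec
            raise ValueError(f"unknown operation {op!r}")
        outputs.append(_finish(out))
    return outputs


def augment_batch(images: list, spec: AugmentSpec,
                  include_originals: bool = True):
    """Expand a batch: originals (optionally) plus one image per
    operation per input."""
    out = []
    for img in images:
        if include_originals:
            out.append(_finish(_as_float(img)))
        out.extend(augment(img, spec))
    return out
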