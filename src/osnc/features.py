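"""Per-pixel attribute vectors for small-neighborhood clustering.

Each pixel is described by m attributes c_q(x).  The default set is
gray level, local mean, local standard deviation, and Sobel gradient
magnitude — standard, reproducible proxies for the gray/peak/valley/
edge descriptors the clustering stage operates on.  Every attribute
plane is min-max normalized to [0, 1] over the image so the weighted
range-normalized distance of the classifier is well scaled; a constant
plane maps to 0.

Borders use reflect padding so no artificial edges appear at the frame.
The attribute list is pluggable: register a callable taking ``(image
as float array, window)`` and returning a same-shaped float plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from osnc.errors import ConfigurationError, InputError

__all__ = [
    "FeatureConfig",
    "FeatureStack",
    "extract_features",
    "flatten_samples",
    "register_attribute",
    "DEFAULT_ATTRIBUTES",
]


def _attr_gray(img: np.ndarray, window: int) -> np.ndarray:
    return img


def _attr_local_mean(img: np.ndarray, window: int) -> np.ndarray:
    return ndimage.uniform_filter(img, size=window, mode="reflect")


def _attr_local_std(img: np.ndarray, window: int) -> np.ndarray:
    mean = ndimage.uniform_filter(img, size=window, mode="reflect")
    sq = ndimage.uniform_filter(img * img, size=window, mode="reflect")
    return np.sqrt(np.maximum(sq - mean * mean, 0.0))


def _attr_gradient(img: np.ndarray, window: int) -> np.ndarray:
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    return np.hypot(gy, gx)


_REGISTRY: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "gray": _attr_gray,
    "local_mean": _attr_local_mean,
    "local_std": _attr_local_std,
    "gradient": _attr_gradient,
}

DEFAULT_ATTRIBUTES = ("gray", "local_mean", "local_std", "gradient")


def register_attribute(name: str, fn: Callable[[np.ndarray, int], np.ndarray]) -> None:
    """Register a custom attribute extractor under ``name``."""
    _REGISTRY[name] = fn


@dataclass(frozen=True)
class FeatureConfig:
    attributes: tuple[str, ...] = DEFAULT_ATTRIBUTES
    window: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        if len(self.attributes) < 1:
            raise ConfigurationError("need at least one attribute")
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be an odd integer >= 3")
        unknown = [a for a in self.attributes if a not in _REGISTRY]
        if unknown:
            raise ConfigurationError(
                f"unknown attribute(s) {unknown}; known: {sorted(_REGISTRY)}"
            )


@dataclass
class FeatureStack:
    """M x N x m stack of attribute values, each plane in [0, 1]."""

    values: np.ndarray
    attribute_names: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def extract_features(image: np.ndarray, config: FeatureConfig | None = None) -> FeatureStack:
    """Compute the per-pixel attribute stack for a grayscale image.

    Each attribute plane is min-max normalized over the image; a plane
    with zero range (no variation) becomes identically 0.
    """
    if config is None:
        config = FeatureConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InputError(f"expected a nonempty 2-D image, got shape {img.shape}")
    planes = []
    for name in config.attributes:
        plane = _REGISTRY[name](img, config.window).astype(float)
        lo, hi = float(plane.min()), float(plane.max())
        if hi > lo:
            plane = (plane - lo) / (hi - lo)
        else:
            plane = np.zeros_like(plane)
        planes.append(plane)
    return FeatureStack(values=np.stack(planes, axis=-1), attribute_names=config.attributes)


def flatten_samples(stack: FeatureStack, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Row-major strided traversal of the stack.

    Returns ``(features, coords)`` where ``features`` is an
    ``ceil(M/stride)*ceil(N/stride) x m`` array and ``coords`` the
    matching ``(row, col)`` pixel positions.
    """
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    M, N = stack.shape
    rows = np.arange(0, M, stride)
    cols = np.arange(0, N, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
    feats = stack.values[coords[:, 0], coords[:, 1], :]
    return feats, coords
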