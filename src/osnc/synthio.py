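"""Synthetic defect scenes and grayscale image/mask file I/O.

The generator emulates inspection imagery of bright convex objects
(dumpling-like blobs) on a uniform background, with three defect
phenotypes carved into the objects:

* ``crack``    — a thin (1–2 px) dark random-walk polyline;
* ``stain``    — a darker filled ellipse;
* ``breakage`` — a disk removed at the object boundary (a "bite").

Every scene carries an exact ground-truth mask with three semantic
labels: 0 = background, 1 = object, 2 = defect.  Generation is a pure
function of the spec (including its seed), so scenes are reproducible
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from osnc.errors import ConfigurationError, ImageIOError

__all__ = [
    "SceneSpec",
    "DefectSpec",
    "LabeledScene",
    "generate_scene",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
]

LABEL_NAMES = {0: "background", 1: "object", 2: "defect"}

# ITU-R BT.601 luma weights, used when collapsing color inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DefectSpec:
    """One defect to carve into a randomly chosen object.

    Parameters
    ----------
    kind : {"crack", "stain", "breakage"}
        Defect phenotype.
    intensity_offset : int
        Gray-level shift applied to defect pixels (negative = darker).
        Ignored for ``breakage``, which exposes the background.
    size : int
        Approximate extent in pixels: walk length for cracks, target
        area for stains, bite radius for breakages.
    """

    kind: str
    intensity_offset: int = -90
    size: int = 60

    def __post_init__(self) -> None:
        if self.kind not in ("crack", "stain", "breakage"):
            raise ConfigurationError(f"unknown defect kind {self.kind!r}")
        if self.size < 1:
            raise ConfigurationError("defect size must be >= 1")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic inspection scene.

    Defaults portray a bright object (gray ~200) on a dark background
    (gray ~40) with moderate sensor noise, mimicking a dark-background
    conveyor-belt image of a convex food item.
    """

    width: int = 128
    height: int = 128
    background_level: int = 40
    n_objects: int = 2
    object_radius: tuple[int, int] = (18, 30)
    object_level: int = 200
    defects: tuple[DefectSpec, ...] = field(default_factory=tuple)
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ConfigurationError("scene dimensions must be >= 16 pixels")
        for name in ("background_level", "object_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{name}={v} outside [0, 255]")
        if self.n_objects < 0:
            raise ConfigurationError("n_objects must be >= 0")
        rmin, rmax = self.object_radius
        if not (1 <= rmin <= rmax):
            raise ConfigurationError("object_radius must satisfy 1 <= min <= max")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        object.__setattr__(self, "defects", tuple(self.defects))


@dataclass
class LabeledScene:
    """A generated image together with its exact ground-truth mask."""

    image: np.ndarray  # uint8, H x W
    truth: np.ndarray  # uint8 labels {0, 1, 2}, same shape

    def __post_init__(self) -> None:
        if self.image.shape != self.truth.shape:
            raise ConfigurationError("image and truth must share a shape")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_objects(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, list[dict]]:
    """Draw non-overlapping disks; returns object mask and per-object geometry."""
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    placed: list[dict] = []
    rmin, rmax = spec.object_radius
    for _ in range(spec.n_objects):
        for _attempt in range(200):
            r = float(rng.uniform(rmin, rmax))
            cy = float(rng.uniform(r + 1, h - r - 1)) if h > 2 * r + 2 else h / 2
            cx = float(rng.uniform(r + 1, w - r - 1)) if w > 2 * r + 2 else w / 2
            ok = all(
                (cy - p["cy"]) ** 2 + (cx - p["cx"]) ** 2 > (r + p["r"] + 2) ** 2
                for p in placed
            )
            if ok:
                mask |= _disk_mask((h, w), (cy, cx), r)
                placed.append({"cy": cy, "cx": cx, "r": r})
                break
        # if no free spot is found the object is silently dropped
    return mask, placed


def _crack_mask(
    obj: dict, shape: tuple[int, int], size: int, rng: np.random.Generator
) -> np.ndarray:
    """Thin dark polyline: a random walk started inside the object."""
    mask = np.zeros(shape, dtype=bool)
    r = obj["r"]
    y = obj["cy"] + rng.uniform(-0.4, 0.4) * r
    x = obj["cx"] + rng.uniform(-0.4, 0.4) * r
    angle = rng.uniform(0, 2 * np.pi)
    thick = int(rng.integers(1, 3))  # 1-2 px wide
    for _ in range(size):
        angle += rng.normal(0.0, 0.35)
        y += np.sin(angle)
        x += np.cos(angle)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < shape[0] and 0 <= ix < shape[1]):
            break
        mask[max(0, iy - thick + 1) : iy + 1, max(0, ix - thick + 1) : ix + 1] = True
    return mask


def _stain_mask(
    obj: dict, shape: tuple[int, int], size: int, rng: np.random.Generator
) -> np.ndarray:
    """Darker filled ellipse with area close to ``size`` pixels."""
    # area = pi*a*b; pick aspect, solve for semi-axes
    aspect = float(rng.uniform(0.5, 1.0))
    a = float(np.sqrt(size / (np.pi * aspect)))
    b = a * aspect
    a = min(a, obj["r"] * 0.8)
    b = min(b, obj["r"] * 0.8)
    theta = rng.uniform(0, np.pi)
    cy = obj["cy"] + rng.uniform(-0.3, 0.3) * obj["r"]
    cx = obj["cx"] + rng.uniform(-0.3, 0.3) * obj["r"]
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy, dx = rr - cy, cc - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / max(a, 1.0)) ** 2 + (v / max(b, 1.0)) ** 2 <= 1.0


def _breakage_mask(
    obj: dict, shape: tuple[int, int], size: int, rng: np.random.Generator
) -> np.ndarray:
    """Disk bite centered on the object boundary."""
    angle = rng.uniform(0, 2 * np.pi)
    cy = obj["cy"] + obj["r"] * np.sin(angle)
    cx = obj["cx"] + obj["r"] * np.cos(angle)
    return _disk_mask(shape, (cy, cx), float(size))


def generate_scene(spec: SceneSpec) -> LabeledScene:
    """Render a :class:`SceneSpec` into an image plus ground-truth mask.

    The drawing order is: background, objects, defects (carved into a
    randomly chosen object each), then clipped additive Gaussian noise.
    Crack and stain pixels stay inside their object; breakage removes
    object pixels (those revert to background in both image and truth).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), float(spec.background_level))
    truth = np.zeros((h, w), dtype=np.uint8)

    obj_mask, placed = _place_objects(spec, rng)
    img[obj_mask] = spec.object_level
    truth[obj_mask] = 1

    for d in spec.defects:
        if not placed:
            break
        obj = placed[int(rng.integers(len(placed)))]
        if d.kind == "crack":
            dm = _crack_mask(obj, (h, w), d.size, rng) & obj_mask
            img[dm] = np.clip(spec.object_level + d.intensity_offset, 0, 255)
            truth[dm] = 2
        elif d.kind == "stain":
            dm = _stain_mask(obj, (h, w), d.size, rng) & obj_mask
            img[dm] = np.clip(spec.object_level + d.intensity_offset, 0, 255)
            truth[dm] = 2
        else:  # breakage: the bite exposes background
            dm = _breakage_mask(obj, (h, w), d.size, rng) & obj_mask
            img[dm] = spec.background_level
            truth[dm] = 0
            obj_mask &= ~dm

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledScene(image=img, truth=truth)


def smoothed_noise_texture(
    shape: tuple[int, int] = (256, 256), seed: int = 0, smooth_sigma: float = 3.0
) -> np.ndarray:
    """Seeded natural-looking texture: low-pass-filtered Gaussian noise
    stretched to the full 8-bit range.  Used for sampling-rate studies,
    where a rich gray histogram is needed."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.normal(size=shape), smooth_sigma)
    lo, hi = field_.min(), field_.max()
    if hi == lo:
        return np.zeros(shape, dtype=np.uint8)
    return np.rint((field_ - lo) / (hi - lo) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array.

    Color inputs are converted to luminance with the BT.601 weights
    (0.299 R + 0.587 G + 0.114 B).  16-bit inputs are rescaled to 8-bit.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.dtype != np.uint8:
        arr = arr.astype(float)
        if arr.max() > 255:
            arr = arr / 257.0  # 16-bit -> 8-bit
    return np.clip(np.rint(np.asarray(arr, dtype=float)), 0, 255).astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale image (PNG/PGM/TIFF chosen by suffix)."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ImageIOError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    try:
        iio.imwrite(path, arr.astype(np.uint8))
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as an 8-bit PNG plus a JSON sidecar naming labels."""
    path = Path(path)
    write_image(np.asarray(mask, dtype=np.uint8), path)
    labels = {int(v): LABEL_NAMES.get(int(v), f"class_{int(v)}") for v in np.unique(mask)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({str(k): v for k, v in labels.items()}, indent=2)
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask written by :func:`write_mask`."""
    return read_image(path)
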