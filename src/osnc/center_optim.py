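"""Optimal segmentation points via alternating fuzzy optimization.

Gray levels are clustered by a fuzzy c-means-style scheme in one
dimension: with memberships mu_k(L_ij) summing to 1 per pixel and
scalar distances d_ijk = |L_ij - o_k|, the objective

    B_f = sum_k sum_ij mu_k(L_ij)^r d_ijk^2

is minimized by alternating the center update
o_k = sum mu^r L / sum mu^r with the membership update
mu_k = d^(-2/(r-1)) / sum_k d^(-2/(r-1)).  A pixel coinciding with one
or more centers takes membership 1/#coincident on those and 0
elsewhere.  Iteration stops when max |delta mu| < tol; the recorded
objective is non-increasing because each half-step is an exact
minimizer given the other block.

Initialization is deterministic: by default centers start evenly
spaced over the image's gray range at (k+0.5)/n (``init="range"``),
which keeps them from piling into one dominant histogram mode; the
(k+0.5)/n gray-value quantiles (``init="quantile"``) and a seeded
random init (``init="random"``) are also available.

Segmentation thresholds are convex combinations of adjacent sorted
centers, J_c = beta*o_c + (1-beta)*o_{c+1}, the balanced beta = 0.5
being the default.  ``apply_thresholds`` labels each pixel with the
number of thresholds strictly below its value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from osnc.errors import DegenerateClassError, ParameterError

__all__ = [
    "CenterSet",
    "FitTrace",
    "objective",
    "update_centers",
    "update_membership",
    "fit",
    "thresholds",
    "apply_thresholds",
]

_COINCIDE_EPS = 1e-12


@dataclass
class CenterSet:
    """Fitted segmentation centers (sorted ascending) and thresholds."""

    centers: np.ndarray
    r: float = 2.0
    beta: float = 0.5

    @property
    def thresholds(self) -> np.ndarray:
        return thresholds(self)

    @property
    def n(self) -> int:
        return self.centers.size


@dataclass
class FitTrace:
    objective: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def objective(U: np.ndarray, D: np.ndarray, r: float) -> float:
    """Fuzzy within-class scatter B_f = sum mu^r d^2."""
    if r <= 1:
        raise ParameterError("fuzzy weight index r must be > 1")
    U = np.asarray(U, dtype=float)
    D = np.asarray(D, dtype=float)
    if U.shape != D.shape:
        raise ParameterError(f"shape mismatch {U.shape} vs {D.shape}")
    return float(np.sum(U**r * D**2))


def update_centers(U: np.ndarray, image: np.ndarray, r: float, rng=None) -> np.ndarray:
    """Membership-weighted mean gray level per class, o_k = sum mu^r L / sum mu^r.

    A class whose total weight vanishes is re-seeded at a random
    percentile of the image (seeded via ``rng``) rather than producing
    a NaN center; without an rng the degenerate class raises.
    """
    U = np.asarray(U, dtype=float)
    img = np.asarray(image, dtype=float)
    w = U**r
    denom = w.reshape(U.shape[0], -1).sum(axis=1)
    numer = (w * img[None, ...]).reshape(U.shape[0], -1).sum(axis=1)
    centers = np.empty(U.shape[0])
    for k in range(U.shape[0]):
        if denom[k] <= 0:
            if rng is None:
                raise DegenerateClassError(f"class {k} has zero total membership weight")
            centers[k] = np.percentile(img, float(rng.uniform(0, 100)))
        else:
            centers[k] = numer[k] / denom[k]
    return centers


def update_membership(image: np.ndarray, centers: np.ndarray, r: float) -> np.ndarray:
    """Inverse-distance memberships; exact-hit pixels get crisp membership."""
    if r <= 1:
        raise ParameterError("fuzzy weight index r must be > 1")
    img = np.asarray(image, dtype=float)
    centers = np.asarray(centers, dtype=float)
    n = centers.size
    D = np.abs(img[None, ...] - centers.reshape((n,) + (1,) * img.ndim))
    hit = D <= _COINCIDE_EPS
    any_hit = hit.any(axis=0)
    with np.errstate(divide="ignore"):
        inv = D ** (-2.0 / (r - 1.0))
    inv[:, any_hit] = hit[:, any_hit]
    U = inv / inv.sum(axis=0, keepdims=True)
    return U


def fit(
    image: np.ndarray,
    n: int,
    r: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    init: str = "range",
) -> tuple[CenterSet, np.ndarray, FitTrace]:
    """Alternate center/membership updates until the memberships settle.

    Returns the sorted centers, the membership field (n x image shape,
    per-pixel sums 1), and a per-iteration objective trace.
    """
    if n < 1:
        raise ParameterError("need n >= 1 classes")
    if r <= 1:
        raise ParameterError("fuzzy weight index r must be > 1")
    img = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    if init == "random":
        centers = rng.uniform(img.min(), img.max(), size=n)
    elif init == "quantile":
        centers = np.quantile(img, (np.arange(n) + 0.5) / n)
    elif init == "range":
        lo, hi = float(img.min()), float(img.max())
        centers = lo + (np.arange(n) + 0.5) / n * (hi - lo)
    else:
        raise ParameterError(f"unknown init {init!r}")
    # distinct starting centers keep classes from collapsing immediately
    centers = np.sort(centers)
    for k in range(1, n):
        if centers[k] <= centers[k - 1]:
            centers[k] = centers[k - 1] + 1e-6

    trace = FitTrace()
    U_prev = None
    for it in range(1, max_iter + 1):
        U = update_membership(img, centers, r)
        centers = update_centers(U, img, r, rng=rng)
        D = np.abs(img[None, ...] - centers.reshape((n,) + (1,) * img.ndim))
        trace.objective.append(objective(U, D, r))
        trace.iterations = it
        if U_prev is not None and np.max(np.abs(U - U_prev)) < tol:
            trace.converged = True
            break
        U_prev = U

    order = np.argsort(centers)
    centers = centers[order]
    U = U[order]
    return CenterSet(centers=centers, r=r), U, trace


def thresholds(centers: CenterSet | np.ndarray, beta: float | None = None) -> np.ndarray:
    """Segmentation thresholds between adjacent sorted centers."""
    if isinstance(centers, CenterSet):
        b = centers.beta if beta is None else beta
        c = np.asarray(centers.centers, dtype=float)
    else:
        b = 0.5 if beta is None else beta
        c = np.asarray(centers, dtype=float)
    if not 0 <= b <= 1:
        raise ParameterError("beta must lie in [0, 1]")
    if c.size < 2:
        return np.empty(0)
    return b * c[:-1] + (1 - b) * c[1:]


def apply_thresholds(image: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Label each pixel with the number of thresholds strictly below it."""
    J = np.asarray(J, dtype=float)
    if J.size and np.any(np.diff(J) < 0):
        raise ParameterError("thresholds must be sorted ascending")
    img = np.asarray(image, dtype=float)
    return (img[..., None] > J.reshape((1,) * img.ndim + (-1,))).sum(axis=-1)
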