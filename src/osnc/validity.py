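"""Fuzzy-correlation validity function for choosing the segment count.

For a fuzzy partition of the gray values into alpha classes with
memberships mu_c and centers nu_c, define per class the fuzzy
deviation

    delta_c^2 = sum_ij mu_c(L_ij)^2 |L_ij - nu_c|^2

and between classes the fuzzy relation

    R_kl = sum_ij mu_k mu_l |L_ij - nu_k| |L_ij - nu_l|

whose normalization phi_kl = R_kl / (delta_k delta_l) is a correlation
in [0, 1] by Cauchy-Schwarz (phi_kk = 1 exactly).  A good partition
keeps distinct classes nearly uncorrelated, so the criterion for a
candidate alpha is F_alpha = max_{k != l} phi_kl, and the chosen
segment count alpha* minimizes F_alpha over the candidate range
(smallest alpha on ties).  An over-split image produces two classes
sharing one population — highly correlated — while an under-split one
leaves mixed memberships that also raise phi; the minimum sits at the
natural component count.

The gray metric is the absolute 1-D level difference throughout.  A
degenerate class (delta_c = 0, every supporting pixel exactly at the
center) would make phi undefined; its correlations are reported as 0
with a warning rather than aborting the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from osnc.errors import InputError
from osnc import center_optim

__all__ = [
    "ValidityReport",
    "fuzzy_deviation",
    "fuzzy_relation",
    "fuzzy_correlation",
    "correlation_matrix",
    "select_alpha",
]


@dataclass
class ValidityReport:
    """Criterion values per candidate segment count and the winner."""

    alphas: list[int]
    F: dict[int, float]
    phi: dict[int, np.ndarray]
    centers: dict[int, np.ndarray]
    alpha_star: int

    def as_dict(self) -> dict:
        return {
            "alpha_star": self.alpha_star,
            "F": {str(a): self.F[a] for a in self.alphas},
            "centers": {str(a): self.centers[a].tolist() for a in self.alphas},
        }


def fuzzy_deviation(U: np.ndarray, image: np.ndarray, centers: np.ndarray, c: int) -> float:
    """Squared fuzzy deviation of class c: sum mu_c^2 (L - nu_c)^2."""
    img = np.asarray(image, dtype=float)
    diff = img - float(centers[c])
    return float(np.sum(U[c] ** 2 * diff**2))


def fuzzy_relation(
    U: np.ndarray, image: np.ndarray, centers: np.ndarray, k: int, l: int
) -> float:
    """Fuzzy cross-scatter between classes k and l."""
    img = np.asarray(image, dtype=float)
    return float(
        np.sum(
            U[k] * U[l] * np.abs(img - float(centers[k])) * np.abs(img - float(centers[l]))
        )
    )


def fuzzy_correlation(R_kl: float, delta_k: float, delta_l: float) -> float:
    """Normalized correlation R_kl / (delta_k delta_l); 0 for degenerate classes."""
    if delta_k <= 0 or delta_l <= 0:
        warnings.warn("degenerate fuzzy class (zero deviation); correlation set to 0")
        return 0.0
    return R_kl / (delta_k * delta_l)


def correlation_matrix(U: np.ndarray, image: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Full symmetric phi matrix for one fitted partition."""
    n = len(centers)
    dev = np.array([fuzzy_deviation(U, image, centers, c) for c in range(n)])
    delta = np.sqrt(dev)
    phi = np.empty((n, n))
    for k in range(n):
        for l in range(k, n):
            R = fuzzy_relation(U, image, centers, k, l)
            phi[k, l] = phi[l, k] = fuzzy_correlation(R, delta[k], delta[l])
    return phi


def select_alpha(
    image: np.ndarray,
    alpha_range: tuple[int, int] = (2, 9),
    r: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> ValidityReport:
    """Sweep candidate segment counts and pick the argmin of F_alpha.

    Each candidate alpha is fitted by the alternating fuzzy center
    optimization; its criterion is the largest off-diagonal correlation.
    Ties resolve to the smallest alpha.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise InputError("empty image")
    lo, hi = alpha_range
    if lo < 2:
        raise InputError("alpha_range must start at >= 2")
    alphas = list(range(lo, hi + 1))
    F: dict[int, float] = {}
    phis: dict[int, np.ndarray] = {}
    centers: dict[int, np.ndarray] = {}
    for a in alphas:
        try:
            cs, U, _ = center_optim.fit(img, a, r=r, tol=tol, max_iter=max_iter, seed=seed)
        except Exception as exc:
            raise type(exc)(f"fit failed at alpha={a}: {exc}") from exc
        phi = correlation_matrix(U, img, cs.centers)
        off = phi[~np.eye(a, dtype=bool)]
        F[a] = float(off.max()) if off.size else 0.0
        phis[a] = phi
        centers[a] = cs.centers
    alpha_star = min(alphas, key=lambda a: (F[a], a))
    return ValidityReport(alphas=alphas, F=F, phi=phis, centers=centers, alpha_star=alpha_star)
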