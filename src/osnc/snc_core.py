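"""Small-neighborhood (epsilon-chain) clustering and classification.

Classes are discovered by chain growth: seed a class at the first
unassigned sample, then repeatedly absorb every unassigned sample
lying within radius ``epsilon`` (Euclidean, in normalized feature
space) of the running class mean, recomputing the mean after each
pass, until no sample qualifies; repeat on the remainder.  The same
chain process run per attribute yields attribute weights: an attribute
along which class members stay tightly chained is more discriminative
and receives a larger weight.

A fitted :class:`ClusterModel` classifies new samples by a weighted,
range-normalized city-block distance to each class mean

    d_i(x) = sum_q b_q |c_q(x) - V_iq| / (O_iq_max - O_iq_min)

where the per-attribute range is taken over the class members together
with x, and a zero range contributes nothing (a constant attribute
carries no discriminative information).  Decision weights

    lambda_i = (1 - d_i / sum_j d_j) / (n - 1)

sum to one and decrease strictly with distance, so argmax lambda is
argmin d.  All tie-breaks pick the lowest index, making every run
deterministic for a fixed sample order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from osnc.errors import InputError, ParameterError, ShapeError
from osnc.features import FeatureStack

__all__ = [
    "NeighborhoodParams",
    "ClusterModel",
    "Assignment",
    "neighbor_attribute_center",
    "estimate_attribute_weights",
    "discover_classes",
    "class_distance",
    "assign",
    "segment",
]


@dataclass(frozen=True)
class NeighborhoodParams:
    """Knobs of the chain-growth process.

    epsilon : chain radius in normalized feature space (default 0.1).
    K : number of successor samples averaged into the starting
        attribute center during training (0 = the sample itself).
    max_classes : cap on discovered classes; samples beyond the cap are
        attached to the nearest existing class mean.
    """

    epsilon: float = 0.1
    K: int = 0
    max_classes: int = 32

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be > 0")
        if self.K < 0:
            raise ParameterError("K must be >= 0")
        if self.max_classes < 1:
            raise ParameterError("max_classes must be >= 1")


@dataclass
class ClusterModel:
    """Classes discovered by chain growth plus attribute weights."""

    n: int
    class_means: np.ndarray  # n x m
    attribute_weights: np.ndarray  # m, sums to 1
    class_sizes: np.ndarray  # n
    class_min: np.ndarray  # n x m attribute minima over members
    class_max: np.ndarray  # n x m attribute maxima over members
    densest_count: int = 0
    training_weights: tuple | None = None  # (zeta_q, zeta_p, p)

    @property
    def m(self) -> int:
        return self.class_means.shape[1]


@dataclass
class Assignment:
    class_index: int
    distances: np.ndarray
    weights: np.ndarray


def neighbor_attribute_center(
    samples: np.ndarray, l: int, K: int, q: int
) -> float:
    """Mean of attribute ``q`` over sample ``l`` and its K listed successors."""
    samples = np.asarray(samples, dtype=float)
    L = samples.shape[0]
    if not (0 <= l and l + K < L):
        raise IndexError(f"samples {l}..{l + K} out of range for L={L}")
    return float(samples[l : l + K + 1, q].mean())


def _chain_grow(values: np.ndarray, center: float | np.ndarray, eps: float,
                available: np.ndarray) -> np.ndarray:
    """Grow one chain: absorb every available sample within ``eps`` of the
    running center, recompute the center as the member mean, repeat until
    stable.  Returns a boolean member mask (subset of ``available``)."""
    member = np.zeros(values.shape[0], dtype=bool)
    center = np.atleast_1d(np.asarray(center, dtype=float))
    vals = values if values.ndim == 2 else values[:, None]
    while True:
        dist = np.linalg.norm(vals - center[None, :], axis=1)
        newly = available & ~member & (dist <= eps)
        if not newly.any():
            break
        member |= newly
        center = vals[member].mean(axis=0)
    return member


def estimate_attribute_weights(
    samples: np.ndarray, params: NeighborhoodParams
) -> tuple[np.ndarray, float, int]:
    """Training-stage attribute weights.

    For each attribute q a chain is grown from the starting attribute
    center (the mean over sample 0 and its K successors) with radius
    epsilon; zeta_q is the absorbed fraction s/L.  Returns
    ``(zeta, zeta_p, p)`` with ``p`` the argmax attribute (first index
    on ties).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise InputError("need a nonempty L x m sample array")
    L, m = samples.shape
    K = min(params.K, L - 1)
    avail = np.ones(L, dtype=bool)
    zeta = np.empty(m)
    for q in range(m):
        center = neighbor_attribute_center(samples, 0, K, q)
        member = _chain_grow(samples[:, q], center, params.epsilon, avail)
        zeta[q] = member.sum() / L
    p = int(np.argmax(zeta))
    return zeta, float(zeta[p]), p


def discover_classes(samples: np.ndarray, params: NeighborhoodParams) -> ClusterModel:
    """Partition samples into classes by greedy chain growth.

    Classes are seeded at the first unassigned sample in order; the cap
    ``params.max_classes`` attaches any leftover samples to their
    nearest class mean.  Attribute weights b_q are the largest
    per-class chained fraction found along attribute q, normalized to
    sum 1 so the classifier distance is scale-stable.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise InputError("need a nonempty L x m sample array")
    L, m = samples.shape
    labels = np.full(L, -1, dtype=int)
    unassigned = np.ones(L, dtype=bool)
    n = 0
    while unassigned.any():
        if n >= params.max_classes:
            break
        seed = int(np.flatnonzero(unassigned)[0])
        member = _chain_grow(samples, samples[seed], params.epsilon, unassigned)
        member[seed] = True
        labels[member] = n
        unassigned &= ~member
        n += 1

    means = np.stack([samples[labels == i].mean(axis=0) for i in range(n)])
    if unassigned.any():  # cap reached: nearest-mean attachment
        rest = np.flatnonzero(unassigned)
        d = np.linalg.norm(samples[rest][:, None, :] - means[None, :, :], axis=2)
        labels[rest] = np.argmin(d, axis=1)
        means = np.stack([samples[labels == i].mean(axis=0) for i in range(n)])

    sizes = np.bincount(labels, minlength=n)
    cmin = np.stack([samples[labels == i].min(axis=0) for i in range(n)])
    cmax = np.stack([samples[labels == i].max(axis=0) for i in range(n)])

    # attribute weights: best per-class chained fraction along each attribute
    b = np.zeros(m)
    for i in range(n):
        in_class = labels == i
        Ni = int(sizes[i])
        for q in range(m):
            member = _chain_grow(samples[:, q], means[i, q], params.epsilon, in_class)
            b[q] = max(b[q], member.sum() / Ni)
    total = b.sum()
    b = b / total if total > 0 else np.full(m, 1.0 / m)

    zeta, zeta_p, p = estimate_attribute_weights(samples, params)
    return ClusterModel(
        n=n,
        class_means=means,
        attribute_weights=b,
        class_sizes=sizes,
        class_min=cmin,
        class_max=cmax,
        densest_count=int(sizes.max()),
        training_weights=(zeta, zeta_p, p),
    )


def class_distance(x: np.ndarray, model: ClusterModel, i: int) -> float:
    """Weighted range-normalized distance from sample ``x`` to class ``i``."""
    if not 0 <= i < model.n:
        raise IndexError(f"class index {i} out of range for n={model.n}")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.m,):
        raise ShapeError(f"sample has shape {x.shape}, model expects ({model.m},)")
    lo = np.minimum(model.class_min[i], x)
    hi = np.maximum(model.class_max[i], x)
    rng = hi - lo
    num = model.attribute_weights * np.abs(x - model.class_means[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rng > 0, num / rng, 0.0)
    return float(terms.sum())


def _decision_weights(d: np.ndarray) -> np.ndarray:
    n = d.size
    if n == 1:
        return np.ones(1)
    total = d.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return (1.0 - d / total) / (n - 1)


def assign(x: np.ndarray, model: ClusterModel) -> Assignment:
    """Classify one sample: distances to every class, decision weights,
    and the winning class (lowest index on ties)."""
    d = np.array([class_distance(x, model, i) for i in range(model.n)])
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("non-finite class distances")
    lam = _decision_weights(d)
    return Assignment(class_index=int(np.argmin(d)), distances=d, weights=lam)


def segment(stack: FeatureStack, model: ClusterModel) -> np.ndarray:
    """Per-pixel classification of a feature stack into class labels."""
    if stack.m != model.m:
        raise ShapeError(
            f"stack has m={stack.m} attributes, model expects m={model.m}"
        )
    M, N = stack.shape
    X = stack.values.reshape(-1, model.m)  # P x m
    d_all = np.empty((X.shape[0], model.n))
    for i in range(model.n):
        lo = np.minimum(model.class_min[i][None, :], X)
        hi = np.maximum(model.class_max[i][None, :], X)
        rng = hi - lo
        num = model.attribute_weights[None, :] * np.abs(X - model.class_means[i][None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(rng > 0, num / rng, 0.0)
        d_all[:, i] = terms.sum(axis=1)
    return np.argmin(d_all, axis=1).reshape(M, N)
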