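"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive (explicit
Python loops, no shared code with the package) so they can serve as
independent cross-checks of the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Reference fuzzy c-means on scalar gray levels (double-loop implementation)


def reference_fcm(image, n, r=2.0, tol=1e-5, max_iter=300, init_centers=None):
    """Naive per-pixel-loop fuzzy c-means on gray levels.

    Mirrors the update equations (crisp membership on exact center
    hits) but shares no code with the package.  Returns sorted centers
    and the matching membership array.
    """
    img = np.asarray(image, dtype=float)
    pixels = img.ravel()
    P = pixels.size
    if init_centers is None:
        lo, hi = pixels.min(), pixels.max()
        centers = [lo + (k + 0.5) / n * (hi - lo) for k in range(n)]
    else:
        centers = [float(c) for c in init_centers]
    U = [[0.0] * P for _ in range(n)]
    U_prev = None
    for _ in range(max_iter):
        for p in range(P):
            d = [abs(pixels[p] - centers[k]) for k in range(n)]
            hits = [k for k in range(n) if d[k] <= 1e-12]
            if hits:
                for k in range(n):
                    U[k][p] = 1.0 / len(hits) if k in hits else 0.0
            else:
                inv = [d[k] ** (-2.0 / (r - 1.0)) for k in range(n)]
                s = sum(inv)
                for k in range(n):
                    U[k][p] = inv[k] / s
        for k in range(n):
            num = sum((U[k][p] ** r) * pixels[p] for p in range(P))
            den = sum(U[k][p] ** r for p in range(P))
            if den > 0:
                centers[k] = num / den
        if U_prev is not None:
            dmax = max(
                abs(U[k][p] - U_prev[k][p]) for k in range(n) for p in range(P)
            )
            if dmax < tol:
                break
        U_prev = [row[:] for row in U]
    order = sorted(range(n), key=lambda k: centers[k])
    centers_sorted = np.array([centers[k] for k in order])
    U_sorted = np.array([U[k] for k in order]).reshape((n,) + img.shape)
    return centers_sorted, U_sorted


def loop_objective(U, D, r):
    """Triple-loop fuzzy scatter."""
    total = 0.0
    n = U.shape[0]
    for k in range(n):
        for idx in np.ndindex(U.shape[1:]):
            total += U[(k,) + idx] ** r * D[(k,) + idx] ** 2
    return total


def loop_fuzzy_deviation(U, image, centers, c):
    total = 0.0
    img = np.asarray(image, dtype=float)
    for idx in np.ndindex(img.shape):
        total += U[(c,) + idx] ** 2 * abs(img[idx] - centers[c]) ** 2
    return total


def loop_fuzzy_relation(U, image, centers, k, l):
    total = 0.0
    img = np.asarray(image, dtype=float)
    for idx in np.ndindex(img.shape):
        total += (
            U[(k,) + idx]
            * U[(l,) + idx]
            * abs(img[idx] - centers[k])
            * abs(img[idx] - centers[l])
        )
    return total


def loop_entropy_bits(image):
    """Histogram entropy from first principles (dict counting + math.log2)."""
    counts: dict[int, int] = {}
    flat = np.asarray(image).ravel()
    for v in flat:
        counts[int(v)] = counts.get(int(v), 0) + 1
    total = flat.size
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def loop_chain_clustering(samples, eps):
    """Naive re-simulation of greedy epsilon-chain class discovery."""
    samples = np.asarray(samples, dtype=float)
    L = samples.shape[0]
    labels = [-1] * L
    n = 0
    while any(lab == -1 for lab in labels):
        seed = next(i for i in range(L) if labels[i] == -1)
        members = {seed}
        center = samples[seed].copy()
        changed = True
        while changed:
            changed = False
            newly = [
                i
                for i in range(L)
                if labels[i] == -1
                and i not in members
                and float(np.linalg.norm(samples[i] - center)) <= eps
            ]
            if newly:
                members.update(newly)
                center = samples[sorted(members)].mean(axis=0)
                changed = True
        for i in members:
            labels[i] = n
        n += 1
    return np.array(labels), n
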