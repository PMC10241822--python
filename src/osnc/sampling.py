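"""Resampling-rate selection by relative entropy loss.

Segmentation parameters (centers, thresholds, segment count) can be
estimated on a decimated sample image far cheaper than on the original,
provided the sample keeps "enough" of the gray-histogram information.
Information is measured by Shannon entropy of the 256-bin gray
histogram (base-2, reported in bits; the base cancels in the relative
loss anyway), and the damage done by nearest-neighbor decimation at
rate eta is the relative entropy loss

    delta_eta = |S_1 - S_eta| / S_1        (0 if S_1 = 0)

A variable-step search walks eta until delta_eta first lands inside a
feasibility band [delta_min, delta_max]: below the band the image is
still too faithful and eta shrinks by eta*k; above it eta grows by
eta*(1 - k/2), clamped to 1 (with the step attenuated on repeated
overshoot so the search cannot ping-pong at the ceiling).  The first
feasible rate eta_f is accepted; a floor S0/min(M, N) guarantees the
sampled side length never drops below S0 pixels, giving the final
eta_o.

``is_unimodal`` decides whether the (smoothed) histogram has a single
dominant mode — a degenerate case in which multilevel thresholding is
pointless and the pipeline falls back to a single class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from osnc.errors import InputError, ParameterError

__all__ = [
    "HistogramProbs",
    "SamplingTrace",
    "ComplexityParams",
    "resample",
    "histogram_probs",
    "entropy",
    "relative_entropy_loss",
    "variable_step_search",
    "clamp_rate",
    "complexity",
    "is_unimodal",
]

N_LEVELS = 256


@dataclass
class HistogramProbs:
    """Normalized 256-bin gray-level histogram."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_LEVELS,):
            raise ParameterError(f"expected {N_LEVELS} bins, got {self.p.shape}")


@dataclass
class SamplingTrace:
    """Record of one variable-step search."""

    iterates: list[tuple[float, float, float]] = field(default_factory=list)  # (eta, t, delta)
    eta_f: float = 1.0
    eta_o: float = 1.0
    S1: float = 0.0
    bounds: tuple[float, float] = (0.01, 0.02)
    step_factor: float = 0.5
    S0: int = 32
    feasible: bool = False


@dataclass(frozen=True)
class ComplexityParams:
    H: int
    Ncls: int  # the (N+1) sample-class count
    ksep: int

    def __post_init__(self) -> None:
        if min(self.H, self.Ncls, self.ksep) < 1:
            raise ParameterError("complexity factors must be positive integers")


def resample(image: np.ndarray, eta: float) -> np.ndarray:
    """Nearest-neighbor decimation at linear rate eta in (0, 1].

    Output pixel (i, j) copies input pixel (floor(i/eta), floor(j/eta));
    no interpolation, so the output gray values are a subset of the
    input's.
    """
    if not 0 < eta <= 1:
        raise ParameterError(f"sampling rate eta={eta} outside (0, 1]")
    img = np.asarray(image)
    M, N = img.shape
    M1 = max(1, int(round(eta * M)))
    N1 = max(1, int(round(eta * N)))
    rows = np.minimum((np.arange(M1) / eta).astype(int), M - 1)
    cols = np.minimum((np.arange(N1) / eta).astype(int), N - 1)
    return img[np.ix_(rows, cols)]


def histogram_probs(image: np.ndarray) -> HistogramProbs:
    """Empirical gray-level distribution over the 256 8-bit levels."""
    img = np.asarray(image)
    if img.size == 0:
        raise InputError("empty image")
    counts = np.bincount(img.astype(np.uint8).ravel(), minlength=N_LEVELS)
    return HistogramProbs(p=counts / img.size)


def entropy(p: HistogramProbs | np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log 0 := 0."""
    arr = p.p if isinstance(p, HistogramProbs) else np.asarray(p, dtype=float)
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def relative_entropy_loss(image: np.ndarray, eta: float) -> float:
    """Fractional entropy change caused by decimation at rate eta."""
    S1 = entropy(histogram_probs(image))
    if S1 == 0.0:
        return 0.0
    S_eta = entropy(histogram_probs(resample(image, eta)))
    return abs(S1 - S_eta) / S1


def variable_step_search(
    image: np.ndarray,
    delta_min: float = 0.01,
    delta_max: float = 0.02,
    step_factor: float = 0.5,
    eta_init: float = 0.5,
    max_iter: int = 50,
) -> SamplingTrace:
    """Walk the sampling rate until its entropy loss first becomes feasible.

    Down-steps (loss below the band) use t = eta*k; up-steps (loss above
    the band) use t = eta*(1 - k/2) with the result clamped to 1.  If the
    clamp fires on consecutive up-steps the step fraction is halved so
    the iterate can re-enter the interior.  Returns the trace with
    ``feasible`` False when the budget runs out.
    """
    if not 0 < delta_min < delta_max:
        raise ParameterError("need 0 < delta_min < delta_max")
    if not 0 < step_factor < 1:
        raise ParameterError("need 0 < step_factor < 1")
    if not 0 < eta_init <= 1:
        raise ParameterError("need 0 < eta_init <= 1")
    img = np.asarray(image)
    trace = SamplingTrace(bounds=(delta_min, delta_max), step_factor=step_factor)
    trace.S1 = entropy(histogram_probs(img))
    eta = float(eta_init)
    up_fraction = 1.0 - step_factor / 2.0
    at_ceiling = False
    for _ in range(max_iter):
        delta = relative_entropy_loss(img, eta)
        if delta < delta_min:
            t = eta * step_factor
            trace.iterates.append((eta, -t, delta))
            eta = eta - t
            at_ceiling = False
        elif delta > delta_max:
            t = eta * up_fraction
            new_eta = min(1.0, eta + t)
            if at_ceiling and new_eta >= 1.0:
                up_fraction /= 2.0
                t = eta * up_fraction
                new_eta = min(1.0, eta + t)
            trace.iterates.append((eta, t, delta))
            at_ceiling = new_eta >= 1.0
            eta = new_eta
        else:
            trace.iterates.append((eta, 0.0, delta))
            trace.eta_f = eta
            trace.feasible = True
            return trace
    trace.eta_f = eta
    trace.feasible = False
    return trace


def clamp_rate(eta_f: float, S0: int, M: int, N: int) -> float:
    """Floor the rate so the sampled short side is at least S0 pixels."""
    if min(S0, M, N) <= 0:
        raise ParameterError("S0, M, N must be positive")
    floor = S0 / min(M, N)
    return float(min(1.0, max(eta_f, floor)))


def complexity(params: ComplexityParams) -> int:
    """Nominal operation count of the optimization: steps x classes x separations."""
    return params.H * params.Ncls * params.ksep


def is_unimodal(p: HistogramProbs | np.ndarray, xi_h: float = 0.015, window: int = 5) -> bool:
    """True when the smoothed histogram has exactly one prominent mode.

    The histogram is moving-average smoothed (window 5) and zero-padded
    so boundary modes count; a mode is prominent when its peak
    prominence exceeds the fraction ``xi_h`` of total mass.
    """
    arr = p.p if isinstance(p, HistogramProbs) else np.asarray(p, dtype=float)
    kernel = np.ones(window) / window
    smooth = np.convolve(arr, kernel, mode="same")
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = find_peaks(padded, prominence=xi_h * arr.sum())
    return len(peaks) == 1
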