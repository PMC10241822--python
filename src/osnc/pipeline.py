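"""End-to-end segmentation flow.

Stages, in order:

1. pick the sampling rate: variable-step entropy-loss search on the
   full image, floored so the sampled short side keeps at least S0
   pixels;
2. decimate to the sample image at that rate;
3. if the sample histogram is unimodal (single prominent mode at
   threshold xi_h) the scene is declared degenerate — one class, done;
   otherwise sweep the candidate segment counts with the fuzzy
   validity function and keep alpha*;
4. fit the fuzzy centers at alpha* on the sample image, derive the
   thresholds, and apply them to the FULL-resolution image — sampling
   only ever influences parameter estimation, never the output grid;
5. (hybrid mode) refine ambiguous pixels, those whose gray value lies
   within +/-5 levels of a threshold, by small-neighborhood clustering
   on per-pixel attribute vectors: ambiguous pixels are re-labeled
   with the threshold label of their attribute-cluster's mean gray
   value, which pulls noisy boundary pixels toward their cluster
   consensus.  Pure ``threshold`` and pure ``snc`` modes are also
   available.

The run is deterministic given (image, config, seed).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from osnc import center_optim, evaluation, sampling, snc_core, validity
from osnc.errors import ConfigurationError, InputError
from osnc.features import FeatureConfig, extract_features
from osnc.synthio import read_image

logger = logging.getLogger("osnc")

__all__ = ["PipelineConfig", "RunReport", "run_osnc", "run_batch"]

THRESHOLD_BAND = 5  # gray levels around each threshold treated as ambiguous


@dataclass
class PipelineConfig:
    # sampling-rate search
    delta_min: float = 0.01
    delta_max: float = 0.02
    step_factor: float = 0.5
    eta_init: float = 0.5
    S0: int = 32
    # segment-count sweep
    alpha_min: int = 2
    alpha_max: int = 9
    xi_h: float = 0.015
    # fuzzy optimization
    r: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    beta: float = 0.5
    # small-neighborhood refinement
    epsilon: float = 0.1
    K: int = 0
    stride: int = 2
    refine: bool = True
    mode: str = "hybrid"  # threshold | snc | hybrid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "snc", "hybrid"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 2 <= self.alpha_min <= self.alpha_max:
            raise ConfigurationError("need 2 <= alpha_min <= alpha_max")
        if not 0 <= self.beta <= 1:
            raise ConfigurationError("beta must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML; nested section keys (``fcm.r`` etc.)
        and flat keys are both accepted."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        sections = {
            "sampling": {"delta_min", "delta_max", "step_factor", "eta_init", "S0", "xi_h"},
            "fcm": {"r", "tol", "max_iter", "beta"},
            "snc": {"epsilon", "K", "stride"},
            "validity": {"alpha_min", "alpha_max"},
        }
        for key, val in raw.items():
            if isinstance(val, dict) and key in sections:
                for k, v in val.items():
                    if k not in sections[key]:
                        raise ConfigurationError(f"unknown key {key}.{k}")
                    flat[k] = v
            else:
                flat[key] = val
        known = cls.__dataclass_fields__.keys()
        bad = [k for k in flat if k not in known]
        if bad:
            raise ConfigurationError(f"unknown config key(s) {bad}")
        return cls(**flat)


@dataclass
class RunReport:
    eta_f: float
    eta_o: float
    alpha_star: int
    centers: list[float]
    thresholds: list[float]
    fcm_iterations: int
    search_iterations: int
    degenerate: bool
    refined_pixels: int
    timings: dict[str, float] = field(default_factory=dict)
    validity_F: dict[int, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["validity_F"] = {str(k): v for k, v in d["validity_F"].items()}
        return d


def _refine_with_snc(
    image: np.ndarray, labels: np.ndarray, J: np.ndarray, config: PipelineConfig
) -> tuple[np.ndarray, int]:
    """Re-label pixels near any threshold using attribute-space clustering."""
    img = np.asarray(image, dtype=float)
    band = np.zeros(img.shape, dtype=bool)
    for j in J:
        band |= np.abs(img - j) <= THRESHOLD_BAND
    if not band.any():
        return labels, 0

    stack = extract_features(np.asarray(image), FeatureConfig())
    coords = np.argwhere(band)
    # subsample the band for class discovery; classify every band pixel after
    stride = max(1, config.stride)
    train = coords[::stride]
    params = snc_core.NeighborhoodParams(
        epsilon=config.epsilon, K=config.K, max_classes=32
    )
    feats_train = stack.values[train[:, 0], train[:, 1], :]
    model = snc_core.discover_classes(feats_train, params)

    # threshold label of each cluster's mean raw gray level
    train_gray = img[train[:, 0], train[:, 1]]
    # cluster membership of training pixels: nearest class mean re-assignment
    feats_band = stack.values[coords[:, 0], coords[:, 1], :]
    d_all = np.empty((feats_band.shape[0], model.n))
    for i in range(model.n):
        lo = np.minimum(model.class_min[i][None, :], feats_band)
        hi = np.maximum(model.class_max[i][None, :], feats_band)
        rng = hi - lo
        num = model.attribute_weights[None, :] * np.abs(
            feats_band - model.class_means[i][None, :]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(rng > 0, num / rng, 0.0)
        d_all[:, i] = terms.sum(axis=1)
    band_cls = np.argmin(d_all, axis=1)

    d_train = np.empty((feats_train.shape[0], model.n))
    for i in range(model.n):
        lo = np.minimum(model.class_min[i][None, :], feats_train)
        hi = np.maximum(model.class_max[i][None, :], feats_train)
        rng = hi - lo
        num = model.attribute_weights[None, :] * np.abs(
            feats_train - model.class_means[i][None, :]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(rng > 0, num / rng, 0.0)
        d_train[:, i] = terms.sum(axis=1)
    train_cls = np.argmin(d_train, axis=1)
    cls_gray = np.array(
        [
            train_gray[train_cls == i].mean() if (train_cls == i).any() else img.mean()
            for i in range(model.n)
        ]
    )
    cls_label = center_optim.apply_thresholds(cls_gray, J)

    refined = labels.copy()
    refined[coords[:, 0], coords[:, 1]] = cls_label[band_cls]
    changed = int(np.count_nonzero(refined != labels))
    return refined, changed


def run_osnc(image: np.ndarray, config: PipelineConfig | None = None) -> tuple[np.ndarray, RunReport]:
    """Segment one grayscale image; returns the label mask and a report."""
    if config is None:
        config = PipelineConfig()
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise InputError(f"expected a nonempty 2-D grayscale image, got shape {img.shape}")
    M, N = img.shape
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    trace = sampling.variable_step_search(
        img,
        delta_min=config.delta_min,
        delta_max=config.delta_max,
        step_factor=config.step_factor,
        eta_init=config.eta_init,
    )
    eta_o = sampling.clamp_rate(trace.eta_f, config.S0, M, N)
    trace.eta_o = eta_o
    timings["rate_search"] = time.perf_counter() - t0
    logger.info("sampling rate: eta_f=%.4f eta_o=%.4f feasible=%s", trace.eta_f, eta_o, trace.feasible)

    sample_img = sampling.resample(img, eta_o)

    probs = sampling.histogram_probs(sample_img)
    if is_degenerate := sampling.is_unimodal(probs, xi_h=config.xi_h):
        logger.info("unimodal sample histogram: degenerate single-class scene")
        report = RunReport(
            eta_f=trace.eta_f,
            eta_o=eta_o,
            alpha_star=1,
            centers=[float(np.asarray(img, dtype=float).mean())],
            thresholds=[],
            fcm_iterations=0,
            search_iterations=len(trace.iterates),
            degenerate=True,
            refined_pixels=0,
            timings=timings,
            config=asdict(config),
        )
        return np.zeros(img.shape, dtype=int), report

    t0 = time.perf_counter()
    vr = validity.select_alpha(
        sample_img,
        alpha_range=(config.alpha_min, config.alpha_max),
        r=config.r,
        tol=config.tol,
        max_iter=config.max_iter,
        seed=config.seed,
    )
    timings["alpha_sweep"] = time.perf_counter() - t0
    logger.info("segment count alpha*=%d", vr.alpha_star)

    t0 = time.perf_counter()
    cs, _, fit_trace = center_optim.fit(
        sample_img, vr.alpha_star, r=config.r, tol=config.tol,
        max_iter=config.max_iter, seed=config.seed,
    )
    cs.beta = config.beta
    J = center_optim.thresholds(cs)
    timings["fit"] = time.perf_counter() - t0

    if config.mode == "snc":
        t0 = time.perf_counter()
        stack = extract_features(img, FeatureConfig())
        from osnc.features import flatten_samples

        feats, _ = flatten_samples(stack, stride=max(1, config.stride))
        params = snc_core.NeighborhoodParams(
            epsilon=config.epsilon, K=config.K, max_classes=config.alpha_max
        )
        model = snc_core.discover_classes(feats, params)
        mask = snc_core.segment(stack, model)
        refined = 0
        timings["snc"] = time.perf_counter() - t0
    else:
        mask = center_optim.apply_thresholds(img, J)
        refined = 0
        if config.mode == "hybrid" and config.refine:
            t0 = time.perf_counter()
            mask, refined = _refine_with_snc(img, mask, J, config)
            timings["refine"] = time.perf_counter() - t0

    report = RunReport(
        eta_f=trace.eta_f,
        eta_o=eta_o,
        alpha_star=vr.alpha_star,
        centers=[float(c) for c in cs.centers],
        thresholds=[float(j) for j in J],
        fcm_iterations=fit_trace.iterations,
        search_iterations=len(trace.iterates),
        degenerate=is_degenerate,
        refined_pixels=refined,
        timings=timings,
        validity_F=vr.F,
        config=asdict(config),
    )
    return mask, report


def run_batch(
    inputs, config: PipelineConfig | None = None, truths=None
) -> dict:
    """Run the pipeline over many images and aggregate accuracy.

    ``inputs`` may be file paths or arrays.  When ground-truth masks
    are supplied, each image scores M_s = 1 if the scene-level
    defect-present call matches the truth's, else 0; the aggregate M
    is the mean over scored images.  Per-file failures are collected
    and do not stop the batch.
    """
    if config is None:
        config = PipelineConfig()
    reports: list[dict] = []
    errors: list[dict] = []
    scores: list[float] = []
    truths = list(truths) if truths is not None else [None] * len(list(inputs))
    inputs = list(inputs)
    for idx, item in enumerate(inputs):
        name = str(item) if isinstance(item, (str, Path)) else f"array[{idx}]"
        try:
            img = read_image(item) if isinstance(item, (str, Path)) else np.asarray(item)
            mask, report = run_osnc(img, config)
        except Exception as exc:  # noqa: BLE001 - batch keeps going
            errors.append({"input": name, "error": str(exc)})
            continue
        entry = {"input": name, "report": report.as_dict()}
        truth = truths[idx] if idx < len(truths) else None
        if truth is not None:
            agree = evaluation.mask_agreement(mask, np.asarray(truth))
            pred_call = evaluation.defect_present(mask, defect_label=_defect_pred_label(agree))
            true_call = evaluation.defect_present(np.asarray(truth))
            m_s = evaluation.single_accuracy(int(pred_call == true_call), 1)
            entry["pixel_accuracy"] = agree.pixel_accuracy
            entry["M_s"] = m_s
            scores.append(m_s)
        reports.append(entry)
    summary: dict = {"reports": reports, "errors": errors}
    if scores:
        summary["M"] = evaluation.mean_accuracy(scores)
    return summary


def _defect_pred_label(agree: evaluation.EvalResult) -> int:
    """Predicted label mapped onto the truth's defect label (2), if any."""
    for pl, tl in agree.mapping.items():
        if tl == 2:
            return pl
    return -1
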