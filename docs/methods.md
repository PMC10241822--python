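# Methods

This note documents the model choices behind `osnc`, the defaults and
their units, the numerical conventions, and what the synthetic scenes
can and cannot demonstrate.

## Problem setting

The target imagery is an 8-bit grayscale inspection scene: bright,
roughly convex objects on a uniform background, where quality defects
appear as gray-level anomalies — thin dark cracks, darker stains, or
breakages that expose background at the object boundary.  Segmentation
must isolate the background, object and defect populations without a
labeled training set, quickly enough to run per frame on a conveyor.

## Sampling-rate selection

Decimating the image before parameter estimation buys speed; the cost
is histogram distortion.  Distortion is quantified by the relative
entropy loss δ_η = |S₁ − S_η| / S₁, where S is the Shannon entropy of
the 256-bin gray histogram and S_η the entropy after nearest-neighbor
decimation at linear rate η ∈ (0, 1].  Entropies are computed base-2
and reported in bits; any consistent base cancels in δ_η.  A constant
image has S₁ = 0 and δ is defined as 0 there.

The variable-step search accepts the *first* rate whose loss enters
the band [δ_min, δ_max] rather than hunting the exact infimum: the
sample image only has to be "good enough", and the first feasible rate
costs far fewer loss evaluations.  Update rules: δ below the band
(sample still too faithful) shrinks the rate by t = η·k; δ above it
grows the rate by t = η·(1 − k/2).  The upward step can overshoot 1;
the iterate is clamped there, and if the clamp fires on consecutive
up-steps the step fraction is halved so the search re-enters the
interior instead of ping-ponging at the ceiling.  Defaults: band
[0.01, 0.02], step factor k = 0.5, starting rate η_init = 0.5, at most
50 iterations.  The band and the single-mode threshold below are the
operating restrictions the method is normally run with; the rest were
chosen for reliable termination on 8-bit imagery.

A decimated image must still support histogram analysis, so the final
rate is floored at S₀ / min(M, N) with S₀ = 32 px: the sampled short
side never drops below 32 pixels.  S₀ is interpreted as a minimum
sampled side length; it is exposed in the configuration.

Nearest-neighbor decimation (output pixel (i, j) ← input
(⌊i/η⌋, ⌊j/η⌋)) is deliberate: it preserves the gray-level *set*, so
the resampled histogram is a subsample of the original rather than a
smoothed version of it.  Area or anti-aliased resampling would
manufacture new gray levels and bias the entropy comparison.

## Segment-count selection

For each candidate count α ∈ [2, 9] (configurable) the fuzzy
optimizer below is fitted and the partition is scored by the largest
pairwise fuzzy correlation

    φ_kl = R_kl / (δ_k δ_l),
    δ_c² = Σ_ij μ_c²(L_ij) |L_ij − ν_c|²,
    R_kl = Σ_ij μ_k μ_l |L_ij − ν_k| |L_ij − ν_l|,

with the absolute gray-level difference as the 1-D metric.  By
Cauchy–Schwarz φ_kl ∈ [0, 1] and φ_kk = 1; the criterion uses only the
off-diagonal maximum F(α) = max_{k≠l} φ_kl, and α* = argmin F (the
smallest α on ties).  The fitted fuzzy partition per α is used as-is;
the criterion is not re-optimized over memberships.  A degenerate
class with δ_c = 0 would leave φ undefined; its correlations are set
to 0 with a warning so a single bad candidate cannot abort the sweep.

The sweep runs on the sample image, which is what makes an 8-candidate
sweep affordable.

## Center and threshold optimization

One-dimensional fuzzy clustering of gray levels: memberships
μ_k(L_ij) ≥ 0 with Σ_k μ_k = 1 per pixel, scalar distances
d_ijk = |L_ij − o_k|, objective B_f = Σ μ^r d².  Alternating the two
closed-form block minimizers —

    o_k = Σ μ_k^r L / Σ μ_k^r,
    μ_k = d_ijk^(−2/(r−1)) / Σ_k d_ijk^(−2/(r−1)),

with crisp membership split evenly across centers that coincide with
the pixel value — drives B_f monotonically downward; the trace
recorded after each full iteration is non-increasing up to 1e-9
relative slack.  Convergence is declared when max |Δμ| < tol.

Defaults: fuzzy weight index r = 2 (the standard quadratic choice),
tol = 1e-5, max 300 iterations.  The membership-update exponent uses r
in both numerator and denominator — the self-consistent form in which
the two updates are exact block minimizers of the same objective.

**Initialization.**  Centers start evenly spaced over the image's gray
range at positions (k + 0.5)/n (``init="range"``).  Gray-value
quantile placement was considered and is still available
(``init="quantile"``), but on defect scenes the background holds ~3/4
of the mass, so several quantile-placed centers start inside one
histogram spike and the 1-D optimization — which has local minima on
spiky histograms — converges to a split of the dominant population
while missing a minority (defect) level entirely; that inverts the
validity sweep.  Range placement guarantees every gray-range stratum
starts with a center and is equally deterministic.  A seeded random
init exists for robustness experiments.  A class that loses all its
weight during iteration is re-seeded at a random percentile of the
image (seeded), and the event is visible in the trace.

Thresholds between adjacent sorted centers are J_c = β o_c +
(1 − β) o_{c+1} with β = 0.5 (balanced) by default; labels count the
thresholds strictly below each pixel.  Thresholding always runs on the
full-resolution image: decimation only ever influences parameter
estimation, never the output grid.

## Attribute-space refinement

Thresholding is purely pointwise, so pixels whose value falls near a
threshold are decided by noise.  The hybrid mode re-decides the band
of pixels within ±5 gray levels of any threshold using spatial
context: each pixel carries m = 4 attributes — gray value, 3×3 local
mean, 3×3 local standard deviation, Sobel gradient magnitude — each
min-max normalized to [0, 1] over the image (a constant plane maps
to 0; borders use reflect padding).  The attribute set is pluggable;
these four are standard, reproducible operators covering the
gray/texture/edge axes along which defect pixels differ from their
surroundings, chosen because the wider menu of candidate descriptors
(tone, multimodality, inflection…) has no canonical formulas.

Band pixels (subsampled by `snc.stride`, default 2) are clustered by
ε-chain growth: seed a class at the first unassigned sample, absorb
every unassigned sample within Euclidean radius ε of the running class
mean, recompute the mean, repeat until no sample qualifies, then seed
the next class.  ε defaults to 0.1 in the normalized feature space —
about the scale of the noise-induced spread of one population —
and is configurable; a cap of 32 classes attaches stragglers to their
nearest mean.  The process is deterministic for a fixed sample order
(row-major), and all ties resolve to the lowest index.

Each discovered cluster takes the threshold label of its mean raw gray
level, and every band pixel adopts its cluster's label — pulling noisy
boundary pixels toward their cluster consensus.  By construction the
refinement can only change pixels inside the band.  Two per-attribute
chain statistics are kept on the model: training weights ζ_q (chained
fraction from the attribute's starting center, the most "coherent"
attribute being ζ_p) and the classifier weights b_q (largest per-class
chained fraction along attribute q).  Only b_q enters the classifier
distance; it is renormalized to sum 1 so the distance is stable under
attribute rescaling.  The classifier itself is the weighted
range-normalized city-block distance with per-class ranges extended by
the query sample; a zero range contributes 0, since a constant
attribute cannot discriminate.  Decision weights
λ_i = (1 − d_i/Σd)/(n − 1) sum to 1 and decrease strictly with
distance (uniform when all distances are 0 or n = 1).

Pure-threshold and pure-SNC modes are exposed (`--mode`); hybrid is
the default wiring.

## Degenerate inputs

A sample image whose smoothed histogram (moving average, window 5,
zero-padded so boundary modes count) has a single mode with prominence
above ξ_h = 0.015 of total mass is declared unimodal: multilevel
thresholding is pointless, the pipeline emits a single-class mask and
flags the run as degenerate.  Constant images take the same path (the
entropy-loss search also cannot become feasible there and falls back
to the S₀ floor).

## Synthetic scenes

The generator draws non-overlapping bright disks (default: two disks
of gray 200, radius 18–30 px — a typical conveyor frame shows several
items, and two keep the object population clearly visible in the
histogram) on a uniform dark background (default gray 40),
carves defects — a 1–2 px random-walk crack polyline, a darker
ellipse stain (default offset −90), or a boundary disk breakage that
re-exposes background — and adds clipped additive Gaussian noise
(default σ = 4 gray levels, a typical industrial-camera noise floor).
Truth masks carry three semantic labels (background/object/defect);
cluster-to-label matching at evaluation time is a one-to-one
best-overlap assignment, after which pixel accuracy and per-class IoU
are reported.  Scene-level "defect present" calls require a defect
component of at least 20 px, a proxy for a downstream detection stage
that is out of scope here.

What the scenes do *not* emulate: uneven illumination, shadows and
specularities, textured (wrinkled) object surfaces, out-of-focus blur,
correlated sensor noise, touching objects, and color.  Passing tests
on these scenes demonstrate the algorithmic contracts (normalization
identities, monotone objective, oracle equivalence, count recovery,
entropy-loss trend, end-to-end mask accuracy on well-separated
populations) — not performance on real factory imagery.

## Problem sizes

Tests and the acceptance script run at desk scale: 8×8–16×16 images
for the optimizer oracles, 48×48 mixtures for count recovery, 128×128
scenes for the end-to-end checks, 128–256 px seeded textures for the
entropy-loss studies, and double-loop reference implementations kept
to ≤ 5×5 instances.  These sizes were chosen so every statistical
check repeats over 10–50 seeds while the whole suite stays fast.

## Known limitations

* The ε-chain partition depends on sample order; row-major order makes
  it deterministic but not rotation-invariant.
* The validity function degrades when class populations are extremely
  unbalanced (a minority class below ~1 % of pixels may be absorbed);
  the refinement stage, not the count selector, is what recovers thin
  cracks in that regime.
* The entropy-loss criterion sees only the histogram: decimation that
  destroys spatial structure but preserves the gray distribution is
  invisible to it.
* The single-mode gate is a height-prominence test on the smoothed
  histogram at ξ_h = 0.015 of total mass: a minority population whose
  mass, after noise spreading, yields a smoothed peak shallower than
  that (roughly below ~10 % of pixels at noise σ ≈ 4) is treated as
  part of the dominant mode and the scene takes the single-class
  path.
* β ≠ 0.5 thresholds are supported but untested against any
  asymmetric-population heuristic.
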