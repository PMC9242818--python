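# Methods

This note documents the models and numerics behind `lsradiomics`: what each
stage assumes, which parameters matter and why their defaults are what they
are, and what the synthetic experiments do and do not demonstrate.

## Edge indicator

The smoothed gradient magnitude is `m = |∇(G_σ ∗ I)|`, computed with
Gaussian-derivative filters (`σ` default 1.0 px — small enough to keep the
boundary peak sharp on thin-walled lesions, large enough to suppress
pixel-level noise). The enhanced indicator is

    g(m) = exp(−[ m² + 1/( |I₀²/m² − 1| + 1 ) ]),   g(0) := 1.

The bracketed sensitivity term lies in (0, 1] and equals 1 exactly at
`m = I₀`; it is what lets the contour react to a *chosen* gradient level
rather than only to large gradients. The `m → 0` limit is defined as
`g = 1` (the term vanishes), so flat tissue does not brake the contour. The
classical geodesic indicator `1/(1+m²)` is kept as an ablation baseline.

**Gradient normalization.** Raw CT gradients reach hundreds of HU/px, and
`exp(−m²)` underflows long before that. By default `m` is divided by its
99th percentile over the ROI and `I₀` by the same factor, so both live on a
scale where the boundary peak is ≈ 1 and the formula's shape is preserved.
`normalization="none"` is retained for unit-level work. Output is clamped to
the smallest positive float so `g > 0` strictly even when `exp` underflows.

**Automatic I₀.** Within a user-placed window straddling the boundary, the
gradient values split into a low in-tissue mode and a high boundary tail.
With `x` the mean and `y` the *population* standard deviation (the
deterministic convention fixed here) of `m` in the window, `I₀` is the mean
of values above `x + y`. Averaging the super-threshold tail sits slightly
below the true peak — about 10% low for a window extending ±6 px around the
boundary of the default phantom — which is within the 15% band the
segmentation tolerates: a mild underestimate moves the `m = I₀` locus less
than a pixel outward. A constant window has an empty tail and raises an
estimation error advising a manual `I₀`.

## Level-set evolution

Φ is signed, negative inside, initialised as the exact signed distance to
any closed seed polygon (half-pixel-corrected distance transform, so the
zero crossing lies on the polygon). The descent is

    ∂Φ/∂t = μ·R(Φ) + λ·δ_ε(Φ)·div(g ∇Φ/|∇Φ|) + v·g·δ_ε(Φ)

with the double-well distance-regularisation `R` (drives `|∇Φ| → 1`,
removing re-initialisation), the smoothed Dirac/Heaviside pair
`δ_ε(z) = ε/(π(ε²+z²))`, `H_ε(z) = ½(1 + (2/π)atan(z/ε))`, and central
differences throughout; the area force is localised by `δ_ε`, which with the
regularised (unit-gradient) Φ is the standard stable discretisation for this
flow, so no upwind switch is needed. Mirror (Neumann) boundary conditions
are applied each step.

Defaults: `λ = 5`, `v = −2.5` (negative = inflation, since seeds are placed
inside the lesion; the magnitude is calibrated on noiseless disk phantoms so
the balloon is strong enough to finish inflating within a few hundred
iterations but weak enough that the `∇g` anchor holds it within half a pixel
of the gradient ridge), `μ = 0.2`, `τ = 1` (explicit-scheme stability bound
`τμ < 0.25` enforced), `ε = 1.5` px (covers the sub-pixel band around the
contour). Convergence is declared when the mean per-pixel `|ΔΦ|` falls below
`tol` (default 1e-3) or after `max_iters` (default 1000); the balloon-driven
runs used in the experiments typically ride the iteration cap with
sub-threshold residual motion, which is why the experiment scripts fix the
iteration budget (400–500) explicitly. Non-finite Φ raises a numerical
error naming the iteration.

The geodesic energy `λ Σ g δ_ε(Φ)|∇Φ| + v Σ g H_ε(−Φ)` can be recorded per
iteration; on noiseless phantoms it is non-increasing once the time step is
small enough, and the test suite asserts this with a halve-τ-and-retry
policy.

## Volume-fraction metrics

`TPVF = 100·|C_o∩C_t|/|C_t|` and `FPVF = 100·|C_o\C_t|/(|C_d|−|C_t|)`; the
FPVF numerator is the false-positive set (the standard form for an
over-segmentation index). Both are undefined (errors) for an empty
reference or an analysis region no larger than the reference. FPVF scales
with the analysis region: all reported numbers use the full phantom raster
as `C_d`, which corresponds to the generously cropped rectangular ROI a
user draws around a lesion.

## Texture features

Gray-level standardization precedes everything: in-mask intensities are
clipped to `μ ± 3σ` (or min–max) and linearly quantized to 64 levels —
6-bit quantization with the 3σ clip is the convention of the texture
software lineage this pipeline follows. The 271-feature default schema is:

| family   | count | definition notes |
|----------|------:|------------------|
| GLCM     | 220   | 11 features (angular second moment, contrast, correlation, sum of squares, inverse difference moment, sum average/variance/entropy, entropy, difference variance/entropy) per symmetric, unit-normalized matrix; distances 1–5 × directions 0/45/90/135°; out-of-mask pixels excluded via a sentinel level; natural-log entropies; 0-based level indices |
| RLM      | 20    | short/long-run emphasis, gray-level and run-length nonuniformity, run percentage (runs/pixels), per direction |
| histogram| 9     | mean, variance, skewness, excess kurtosis, percentiles 1/10/50/90/99 of the quantized levels |
| gradient | 5     | mean/variance/skewness/kurtosis of the central-difference gradient magnitude over interior in-mask pixels, plus the nonzero fraction |
| AR       | 5     | least-squares θ₁–θ₄ of the causal W/NW/N/NE model (an intercept is included so the fit is exact on noiseless recursions) and the residual RMS σ |
| wavelet  | 12    | mean squared coefficient of LL/LH/HL/HH at 3 Haar levels, bounding box mean-filled outside the mask |

Matrices or families that cannot be computed (ROI thinner than a GLCM
distance, too small for the AR neighbourhood or a wavelet level) are skipped
with a logged warning rather than padded; degenerate statistics on constant
ROIs (zero variance) are defined as 0. An optional mask erosion emulates the
keep-inside-the-lesion margin used when ROIs are drawn manually.

## Feature selection

* **Fisher coefficient** `F = D/V` with prior-weighted between-class
  variance `D` and pooled within-class (population) variance `V`; `V = 0`
  with `D > 0` maps to +inf so perfectly separating features rank first.
  Scale-invariant exactly.
* **POE+ACC**: greedy forward selection minimising
  `POE(f) + mean |r_w(f, s)|` over already-selected `s`, where POE is the
  error of the best single threshold (both polarities, all cuts) and `r_w`
  is the *within-class* Pearson correlation (class means removed; pooled
  correlation is the fallback for class-constant features). The within-class
  form is deliberate: with a strong class effect, every discriminative
  feature is pooled-correlated with every other through the labels alone
  (r ≈ d²/4 / (1+d²/4) ≈ 0.9 at d = 5 SD), so a pooled ACC penalises
  precisely the features worth selecting and caps their score above any
  noise feature's POE; the within-class form measures redundancy beyond the
  class signal while still assigning exact duplicates ACC = 1. Ties break
  lexicographically.
* **Mutual information** between the label and the feature discretised into
  10 equal-frequency bins, in bits; invariant to monotone transforms,
  0 for constants. The small-sample bias at n = 200 is ≈ 0.03 bits, which
  the null test budgets for.

Top-10 per method; the combined list keeps duplicates (3 × k names) by
default, with deduplication available.

## Classification

All four analyses are validated leave-one-out, with z-scoring computed from
each training fold only (the poisoning test in the suite verifies the
held-out sample never influences its own prediction). RDA is 1-NN on the
z-scored features; PCA keeps components reaching 95% training variance and
runs 1-NN in component space (keeping all components reproduces RDA exactly,
by rotation invariance); LDA is the pooled-covariance Fisher discriminant
with a ridge fallback when the covariance is singular (p ≥ n); NDA is a
single-hidden-layer network (6 logistic units, L-BFGS, fixed seed), with a
stratified k-fold option used where the analysis is repeated hundreds of
times (permutation nulls) — LOO-MLP there would cost two orders of magnitude
more for the same mean. Results render as `misclassified/total (pp.pp%)`
with half-up rounding at two decimals.

A known property of LOO on no-signal data: removing the held-out sample
tilts the training set against its class, so null MCRs sit slightly *above*
50% (and LDA on a balanced four-blob XOR layout scores far above 50%, which
is the geometry the NDA-beats-LDA comparison exploits).

## Synthetic data: what it does and does not show

The phantom generator produces a two-region lesion (disk, ellipse, or
harmonically-perturbed blob) on a uniform background, with the ideal step
edge blurred at `boundary_softness` (default 1.0 px, the partial-volume
scale of thin CT structures), an optional contiguous angular sector whose
contrast is multiplied by `weak_contrast_factor` (the weak-boundary failure
mode the enhanced indicator targets), and additive Gaussian noise. The peak
boundary gradient has the closed form `h/(s√(2π))` with `s² = softness² +
σ²`, which serves as the independent oracle for the I₀ estimator. Default
contrast is 100 (background 100, lesion 200) with noise 5 (5% of contrast)
in the noisy experiments.

Feature tables are multivariate normal per class: informative columns
shifted by `effect_size` SD (default 5, the planted-recovery condition) and
equicorrelated at 0.3 (a realistic inter-feature correlation that also
exercises the ACC penalty); noise columns are independent standard normal.

What passing these experiments shows: the edge indicator has the claimed
closed-form behaviour; the evolution is stable, energy-decreasing and lands
on the gradient ridge to sub-pixel accuracy; the estimator tracks the
analytic boundary gradient; the selective advantage over the classical
indicator at weak arcs is real and systematic; selection and classification
recover planted structure and are honest under label permutation. What it
does not show: performance under CT reconstruction artefacts, correlated
noise, anatomy-shaped lesions or inter-observer reference variability — and
no claim is made about clinical misclassification rates, which depend on a
patient cohort no synthetic table can stand in for.

## Known limitations

* Strictly 2-D; no multi-phase or 3-D evolution.
* The balloon sign must match the seed placement (inside ⇒ `v < 0`);
  seeding outside the lesion is unsupported.
* GLCM/RLM definitions follow one published convention; other
  implementations differ in level indexing, entropy base and normalisation,
  so absolute feature values are not interchangeable across tools.
* The texture feature count (271) is fixed by this package's default
  schema; comparable tools ship nearby but different counts.
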