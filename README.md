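# lsradiomics

Level-set segmentation of CT lesions with a gradient-tuned edge indicator,
plus a Mazda-style radiomics pipeline: texture features → filter-based
feature selection → four classification analyses reported as
misclassification rates.

## The problem

Lesions in CT — sinus disease is the motivating case — often sit against
surrounding soft tissue with *weak boundaries*: arcs of the lesion contour
whose gradient is far below the rest. Edge-based active contours driven by
the classical geodesic indicator `g(m) = 1/(1 + m²)` (with
`m = |∇(G_σ ∗ I)|` the smoothed gradient magnitude) decay too slowly in `m`;
an inflating contour pushes straight through moderate-gradient arcs and
leaks into the background. Downstream, texture features of the segmented
lesion are used to predict treatment prognosis, so segmentation errors
propagate into the radiomics model.

## The method

**Enhanced edge indicator.** Given a preset (or automatically estimated)
lesion-boundary gradient `I₀`, the indicator

```
g(m) = exp(−[ m² + 1/( |I₀²/m² − 1| + 1 ) ]),    g(0) := 1
```

adds a sensitivity term that attains its maximum (exactly 1) at `m = I₀`, so
`g` dips hardest where the gradient matches the expected boundary — including
weak arcs, if `I₀` is set to their gradient — while `g → 1` on flat regions.

**Automatic I₀.** Inside a user window straddling the boundary, compute the
mean `x` and population standard deviation `y` of `m`; `I₀` is the mean of
the values above the threshold `x + y` (boundary pixels form the upper tail).

**Curve evolution.** The contour is the zero level set of a signed field Φ
(negative inside) evolved by explicit descent of the geodesic energy

```
E(Φ) = λ ∫ g δ_ε(Φ) |∇Φ| dxdy  +  v ∫ g H_ε(−Φ) dxdy,    λ > 0,
```

with a double-well distance-regularisation term (weight μ) that keeps Φ
near a signed distance function. `v < 0` inflates the seed contour (any
closed curve inside the lesion, e.g. a triangle); `g` throttles the
inflation and anchors the contour at the boundary.

**Evaluation.** Against a reference mask `C_t` in an analysis region `C_d`,
a produced mask `C_o` is scored by the true/false-positive volume fractions
`TPVF = 100·|C_o ∩ C_t|/|C_t|` and `FPVF = 100·|C_o \ C_t|/(|C_d| − |C_t|)`.

**Radiomics.** The segmented ROI is gray-standardized (μ ± 3σ clip, 64
levels) and 271 texture features are extracted (GLCM 11 features × 5
distances × 4 directions, run-length 5 × 4 directions, histogram, absolute
gradient, causal autoregressive model, wavelet sub-band energies). Features
are ranked by the Fisher coefficient `F = D/V`, by POE+ACC (greedy single-
threshold error plus within-class correlation penalty), and by mutual
information (equal-frequency bins); the top 10 per method (30 combined) feed
four analyses — RDA (1-NN), PCA + 1-NN, LDA, and NDA (small neural net) —
validated leave-one-out and reported as `misclassified/total (percent)`.

Everything is exercised on synthetic phantoms (two-region lesions with
controllable boundary softness, weak-contrast arcs and noise; labelled
feature tables with planted effects), so the whole pipeline is testable
without patient data.

## Worked example

```python
import lsradiomics as lr
from lsradiomics import levelset, metrics
from lsradiomics.segment import segment, triangle_seed

spec = lr.PhantomSpec(noise_sd=5.0, seed=7)        # disk lesion, 5% noise
img, truth = lr.generate_phantom(spec)
res = segment(img, triangle_seed((64, 64), 8), sigma=1.0,
              i0="auto", i0_window=(38, 54, 50, 74),
              evolve_params=levelset.EvolveParams(max_iters=500))
print(f"I0 = {res.i0:.2f}")
ev = metrics.evaluate(res.mask, truth)
print(f"TPVF = {ev.tpvf:.2f}%  FPVF = {ev.fpvf:.3f}%")
```

prints

```
I0 = 25.09
TPVF = 99.60%  FPVF = 0.013%
```

i.e. the estimated boundary gradient is within ~11% of the phantom's
analytic peak (28.21), 99.6% of the true lesion is captured and essentially
nothing outside it is included. Continuing with a synthetic 100-sample
feature table (planted 1.2-SD effects), selection + classification print the
full misclassification-rate grid:

```
        RDA              PCA              LDA              NDA
fisher  13/100 (13.00%)  17/100 (17.00%)  15/100 (15.00%)  16/100 (16.00%)
poeacc  13/100 (13.00%)  14/100 (14.00%)  14/100 (14.00%)  13/100 (13.00%)
mi      13/100 (13.00%)  17/100 (17.00%)  15/100 (15.00%)  17/100 (17.00%)
```

Each cell is `misclassified/total (percent)` under leave-one-out validation;
lower is better.

The same workflow is available from the shell:

```
lsradiomics pipeline demo --out demo_run --seed 0
lsradiomics segment --image slice.png --seed poly.csv --i0 auto --out mask.png
lsradiomics evaluate --pred mask.png --truth gold.png
```

## Documentation

See `docs/methods.md` for the model details, parameter defaults, numerical
choices, and what the phantom experiments do and do not demonstrate.
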