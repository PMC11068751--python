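# dielact

Quantifying how much of the day a wild population spends active — and
*when* — from camera-trap detection times, and how both respond to
landscape context. `dielact` was built for replicated camera-trap
studies of white-tailed deer across landscape gradients (deer density,
anthropogenic development, woody-browse and agricultural food), but the
machinery applies to any diel-activity analysis with detections nested
in replicate sampling units.

## What it computes

**Activity level.** Detection clock times are first *double-anchored*:
each day's times are rescaled piecewise-linearly on the diel circle so
that that day's sunrise and sunset land on the study-average anchors,
which aligns crepuscular activity across days and sites. A von Mises
circular kernel density f̂ is fitted to the anchored times (plug-in
bandwidth from trigonometric moments, Taylor's rule), and the activity
level is the ratio-to-peak estimator

    p̂ = 1 / (2π · max f̂),

with nonparametric bootstrap SEs and percentile intervals. For a true
von Mises(κ) density, p = I₀(κ)e^(−κ).

**Activity pattern.** The diel circle is tiled into night / morning /
daytime / evening (morning and evening are sunrise ± 2 h and
sunset ± 2 h) and the fraction of activity in each category is
∫ f̂(x) dx over the category's arc — a 4-part composition.

**Regional comparisons.** Pooled per-region levels and fractions are
compared with Wald statistics W = (AL₁ − AL₂)² / (SE₁² + SE₂²) on
χ²(1), with Holm step-down adjustment within each comparison family.

**Landscape regressions.** Per-landscape levels (≥ 100 detections) are
modelled by a hierarchical beta regression with logit link, Student-t
(3, 0, 2.5) priors, and a region random intercept; the composition by
a hierarchical Dirichlet regression with softmax link and night as the
reference category. Candidate models are weighted by PSIS-LOO stacking,
summarized with evidence ratios (support when < 3) and 89% equal-tailed
credible intervals.

**Synthetic data.** `dielact.synthetic_data` generates the whole study
design — covariates, regression-linked true levels/compositions,
circular densities, and camera-level detection tables — with the
*realized* density's level and composition recorded as ground truth.

## Worked example

```python
import numpy as np
from dielact import fit_circular_kde, activity_level, chi2_pvalue, holm_adjust

# Activity level of a von Mises(kappa=2) population: truth I0(2)e^-2 = 0.3085
rng = np.random.default_rng(202)
times = rng.vonmises(np.pi, 2.0, 5000) % (2 * np.pi)
level = activity_level(fit_circular_kde(times))
print(f"estimated activity level: {level.estimate:.3f}")

# Regional Wald comparisons (published statistics), Holm-adjusted
p = holm_adjust([chi2_pvalue(w) for w in (1.27, 2.60, 8.60)])
print("adjusted P:", [f"{x:.2g}" for x in p])
```

prints

```
estimated activity level: 0.309
adjusted P: ['0.26', '0.21', '0.01']
```

i.e. the kernel estimate recovers the closed-form level to ~0.001, and
only the third regional contrast (the largest Wald statistic) remains
significant after multiplicity adjustment.

The full pipeline runs from the command line:

```bash
dielact simulate --seed 2 --out sim/            # synthetic study + ground truth
dielact regional  --detections sim/detections.csv --out results/
dielact landscape --detections sim/detections.csv \
                  --covariates sim/covariates.csv --out results/
dielact report    --results results/
```

`regional` writes per-region levels/compositions and the Holm-adjusted
Wald table; `landscape` writes the 9-model comparison (6 level models,
3 pattern models) with stacking weights, evidence ratios, and
coefficient tables with 89% intervals.

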