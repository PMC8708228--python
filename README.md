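# mandiblefit

Statistical shape modelling and virtual fit analysis of **preformed
mandibular osteosynthesis plates**.

Preformed plates are pre-bent to population anatomy so a surgeon can fix a
reduced mandibular fracture without intraoperative plate bending. Whether
that works depends on two computations this package implements end to end:

1. **Design** — estimate a statistical shape model (SSM) per anatomical
   region (symphysis, body, angle, condyle) from a corresponded mesh
   cohort, and read plate design surfaces for sizes S/M/L off the model's
   allometric axis;
2. **Evaluation** — virtually fit every plate to every specimen of a test
   cohort under a tolerance-constrained rigid best-fit and report the
   percentage of cases in which the plate-to-bone gap stays within 1.5 mm.

It is aimed at researchers in computational anatomy / surgical device
design who want a reproducible, fully tested reference pipeline. Clinical
CT cohorts are not redistributable, so the package ships a synthetic
mandible-cohort generator with known ground truth (dominant allometric
mode, secondary shape modes, sex/population group structure, bilateral
symmetry) on which every stage is validated.

## The model

Given corresponded specimens, each region's vertex subset
`X_k ∈ R^{p×3}` is aligned by **generalized Procrustes analysis without
scaling** (size stays in the data), then decomposed by PCA:

    x_k = x̄ + Σ_j c_kj v_j,     c_k = scores, v_j = components

Because size is retained, the first component carries **allometry** (shape
change associated with size, including sexual dimorphism). The region shape
is regressed on the PC1 score s,

    x(s) = β₀ + β₁ s,       β₁[i] = Cov(x[i], s) / Var(s),

and the S/M/L design surfaces are `x(s_q)` at the 20/50/80% empirical
quantiles `s_q` of the PC1 scores — so sizes differ in shape, not just
scale. Plates are sampled on these surfaces as two bars (tension and
pressure zones) joined by connectors; fitting uses a three-point initial
positioning, a deterministic keep-out correction (mental foramen), and an
iterative-closest-point best-fit in which penetration beyond 0.1 mm is
penalised and finally projected out. A plate *fits* a specimen when the
maximum back-surface gap is ≤ 1.5 mm.

## Worked example

```python
import numpy as np
from mandiblefit import (
    sample_cohort, training_cohort_config, test_cohort_config,
    build_region_models, design_plate_family, run_study, results_to_frame,
    summarize, table1_text,
)

# 127 synthetic training specimens (37 European / 90 Asian, both sexes)
train, truth = sample_cohort(training_cohort_config(seed=0, noise_sd=0.05))
models = build_region_models(train, truth.template)

ev = models["body"].pca.explained_variance_
print(f"body region: PC1 explains {100*ev[0]/ev.sum():.1f}% of variance")
print(f"PC1 score vs true size mode: r = "
      f"{np.corrcoef(models['body'].pca.scores_[:,0], truth.scores[:,0])[0,1]:.3f}")

plates = design_plate_family(models)          # 11 type-size designs
test_cfg = test_cohort_config(seed=1, noise_sd=0.05)
test_cfg.n_specimens, test_cfg.demographics = 10, None
test, _ = sample_cohort(test_cfg)
results = run_study(plates, test, truth.template)   # 20 tests per specimen
print(table1_text(summarize(results_to_frame(results, test.metadata))))
```

prints

```
body region: PC1 explains 98.5% of variance
PC1 score vs true size mode: r = 0.994
                    Size L  Size M  Size S   Total
Condyle plate          100     100     100     100
Body plate             100     100     100     100
Ramus plate            100     100     100     100
Symphysis plate        100     100       -     100

Overall fit: 100.0% (200/200 tests)
```

The PC1 axis recovers the generator's true allometric scores almost
perfectly, and the resulting plates fit essentially all specimens of this
smooth synthetic population — clinical cohorts, with real anatomical
irregularity that the generator deliberately does not model, yield much
lower per-cell rates (see `docs/methods.md` for what the synthetic
validation does and does not show). Doubling the cohort's shape variance
lowers the fit percentages, never raises them.

A `mandiblefit` command-line interface exposes the same pipeline as
subcommands (`simulate`, `register`, `model`, `design`, `fit`, `report`)
exchanging STL/CSV/JSON artefacts.

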