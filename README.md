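# scolprog

From scoliotic spine geometry to trunk biomechanics to progression-risk
classification in mild adolescent idiopathic scoliosis (AIS).

A major clinical question in AIS is whether a mild curve (Cobb angle
10–25°) seen at first examination will progress. `scolprog` implements, as
a tested and fully synthetic-data-driven pipeline, the complete analysis
chain of a progression-prediction study design:

1. **Cohort synthesis** (`scolprog.cohort`, `scolprog.calibration`) — a
   generator of labelled baseline cohorts (60 stable / 40 progressive by
   default) calibrated to published group statistics: per-group mean (SD)
   of age, Risser sign, nine geometrical descriptors and eleven
   biomechanical predictors, Lenke-type and sex proportions, and the
   published Cobb ↔ lateral-shear correlations. Two modes: direct
   23-dimensional predictor vectors, or full per-vertebra orientation
   chains T1–L5.
2. **Spine geometry** (`scolprog.geometry`) — the nine standard
   descriptors from vertebral orientations: thoracic kyphosis TK (T1–T12),
   lumbar lordosis LL (L1–S1), sacral slope SS, pelvic incidence
   PI = SS + pelvic tilt, number of scoliotic curves, Cobb angle of the
   most severe curve (end-vertebra inclination difference), curve sagittal
   angle, largest vertebral axial rotation in the curve, and an
   approximate Lenke type; plus the torsion index.
3. **Musculoskeletal simulation** (`scolprog.msk`) — a subject-specific
   rigid-body chain in the replicated relaxed upright posture, with
   erector spinae (ES) and multifidus (MF) fascicles (maximum force =
   PCSA × 90 N/cm², PCSA scaled with age), solved by inverse statics:
   minimise Σ activationᵖ (p = 3) subject to three moment-equilibrium
   equations per spherical joint, activations ∈ [0, 1].
4. **Biomechanical predictors** (`scolprog.features`) — |F_lat| (the
   lateral shear of the intervertebral reaction in the local vertebral
   frame) at the upper end, apex and lower end of the main curve, and the
   normalized activity ratios nES, nMF = (convex − concave)/(convex +
   concave) at those levels and along the whole curve: 11 values.
5. **Classification experiment** (`scolprog.prediction`,
   `scolprog.stats`) — the two-phase harness: *pre-selection* screens six
   classifiers (SVM, PDA, BAY, DET, KNN, ENS) by 10 × stratified 4-fold CV
   (40 accuracies each, shared folds); *comparison* evaluates the selected
   classifiers on 100 stratified 80/20 splits for the reduced
   (12 anthropometric + geometrical predictors) versus full (23,
   adding the biomechanical block) sets, with per-algorithm Wilcoxon
   rank-sum tests, Kruskal–Wallis with Tukey–Kramer post-hocs, and
   decision-tree predictor importance.

## Worked example

```python
import numpy as np
from scolprog import (CohortConfig, generate_cohort, cohort_to_frame,
                      assemble_predictors, preselect, compare_models)

df = cohort_to_frame(generate_cohort(CohortConfig(seed=1)))
reduced = assemble_predictors(df, "reduced")   # 12 predictors
full = assemble_predictors(df, "full")         # 23 predictors

pre = preselect(reduced, ("BAY",), seed=11)
print("BAY median accuracy:", np.median(pre.accuracy["BAY"]))

comp = compare_models(reduced, full, algorithms=("PDA", "BAY", "ENS"),
                      seed=12)
print("ENS median specificity:",
      np.median(comp.specificity[("ENS", "reduced")]))
```

prints

```
BAY median accuracy: 0.76
ENS median specificity: 0.8333333333333334
```

i.e. on this synthetic cohort the kernel naive Bayes classifies ~76% of
held-out subjects correctly from anthropometric + geometrical predictors
alone, and the bagged-tree ensemble correctly identifies ~10 of the 12
stable subjects in a typical 20-subject test split. Adding the 11
simulated biomechanical predictors leaves the medians essentially
unchanged — they are constructed to reflect curve severity and body size,
information the reduced set already carries.

The same chain is available from the shell:

```bash
scolprog cohort --n-stable 60 --n-progressive 40 --seed 1 --out cohort.csv
scolprog run --seed 1 --mode feature_level --out results/
```

The geometry-level path (`--mode geometry_level`) runs every subject
through the descriptor computations and the inverse-statics solver instead
of sampling predictors directly.

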