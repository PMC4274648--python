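# dtdct

CT feature scoring and diagnostic-accuracy evaluation for **incidentally
detected diffuse thyroid disease (DTD)** — Hashimoto thyroiditis,
non-Hashimoto lymphocytic thyroiditis and diffuse hyperplasia found on neck
CT performed for other reasons.

On neck CT, a diseased gland tends to show low parenchymal attenuation,
inhomogeneous attenuation, increased glandular size, a lobulated margin and
inhomogeneous enhancement.  The package implements the rule-based scoring
system built on those five features, together with the full
diagnostic-accuracy machinery used to evaluate it, and two kinds of
synthetic data — tabular patient cohorts and 3-D CT phantoms — so that every
index of the underlying 209-patient study (157 normal glands, 52 DTD) can be
recomputed with no access to patient images.

It is aimed at researchers who work on rule-based radiological classifiers
and need a fully reproducible test bed: statisticians checking
diagnostic-accuracy arithmetic, and imaging scientists validating
measurement code against phantoms with known ground truth.

## The scoring rule

Five binary abnormality flags are read off a patient's CT feature profile:

| flag | rule |
|---|---|
| low attenuation | mean nonenhanced HU < 100 (iso: 100–180, high: > 180) |
| inhomogeneous attenuation | attenuation pattern = inhomogeneous |
| increased size | average AP lobe diameter > 2 cm (normal 1–2, decreased < 1) |
| lobulated margin | margin = lobulated |
| inhomogeneous enhancement | enhancement pattern = inhomogeneous |

A gland is called DTD-positive when at least *k* flags are set (default
*k* = 3).  Heterogeneous patterns and a decreased gland are recorded but
never counted; the enhancement degree (enhanced − nonenhanced HU) is
computed but carries no flag, since no usable enhancement cut-off separates
the classes.  From the 2×2 confusion table the usual indices follow —
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV, accuracy — and,
for a single binary rule, the ROC area reduces to the two-point trapezoid
A<sub>z</sub> = (sensitivity + specificity)/2.  Hanley–McNeil standard
errors give the AUC confidence intervals; Pearson chi-square compares
feature frequencies between classes; a univariate logistic fit (IRLS)
models disease probability against HU.

## Worked example

```python
from dtdct import reconstruct_fixture_cohort, evaluate_cohort, render_report_text

cohort = reconstruct_fixture_cohort("table4", seed=1)   # 209 patients
report = evaluate_cohort(cohort, seed=1)
print(render_report_text(report))
```

prints, among the cut-off, per-feature and count-threshold tables:

```
3 or more  29/52 (55.8)  150/157 (95.5)  29/36 (80.6)  150/173 (86.7)  179/209 (85.6)  0.7566  0.6742-0.8389
best cutoff: 100.0
best count threshold: 3
logistic fit: intercept=2.9826 slope=-0.0394 converged=True
```

Reading the "3 or more" row: of 52 diseased glands 29 are detected
(sensitivity 55.8%), of 157 normal glands 150 are correctly negative
(specificity 95.5%); 80.6% of positive calls are true disease, 86.7% of
negative calls are truly normal, 179 of 209 patients are classified
correctly (accuracy 85.6%), and the two-point ROC area is 0.7566.  The
best HU cut-off (100) is chosen by ROC area over {80, 90, 100}; the best
count threshold (3) by accuracy over k = 1..5.  The same pipeline is
available from the shell (`dtdct simulate-cohort`, `simulate-phantoms`,
`extract-features`, `classify`, `evaluate`, `reproduce-tables`).

The phantom half generates NIfTI neck-CT volumes — two elliptical-cylinder
lobes around an air trachea, with configurable noise, mottling fields,
margin undulation and focal lesions — and measures them exactly as a reader
would (circular-ROI HU averaged over lobes, AP diameter, convexity-based
margin, pattern rules).  On noiseless phantoms every extracted feature
equals its generating ground truth, so the imaging pipeline and the tabular
pipeline produce identical evaluation reports.

## Layout

- `src/dtdct/cohort.py` — feature profiles, patient records, the random
  cohort generator, the deterministic fixture reconstruction, CSV IO
- `src/dtdct/scoring.py` — HU banding, abnormality flags, the k-or-more rule
- `src/dtdct/phantom.py` — phantom generation, ROI/size/margin/pattern
  measurement, NIfTI IO
- `src/dtdct/diagnostics.py` — confusion counts, indices, two-point AUC,
  Hanley–McNeil CI, cut-off selection, chi-square, logistic fit
- `src/dtdct/reporting.py`, `src/dtdct/cli.py` — report assembly and the
  command-line stages
- `docs/methods.md` — models, assumptions, calibration and limitations
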