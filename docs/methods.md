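# Methods

## The scoring system

A patient's CT feature profile holds two continuous measurements (mean
parenchymal HU on nonenhanced and contrast-enhanced CT, each averaged over
the two lobes) and five categorical readings.  Five abnormality flags are
derived — low attenuation (HU < 100), inhomogeneous attenuation pattern,
increased size (average AP diameter > 2 cm), lobulated margin,
inhomogeneous enhancement pattern — and the classifier calls DTD when at
least *k* flags are set, default *k* = 3.

Boundary semantics deserve care.  The attenuation *banding* is strict at
100 (low iff HU < 100; exactly 100 is iso), while the cut-off *sweep*
tables use "value or less".  Both conventions are supported through a
configuration switch (`comparison` ∈ {lt, le}); they differ only for
patients whose HU ties a cutoff exactly.  The study data themselves imply
one normal gland at exactly 100 HU (27 low normals in the frequency table
vs 28 normals at "100 or less" in the cut-off table), and the fixtures
reproduce that tie patient.

Heterogeneous patterns and decreased glands raise no flag: only the five
named features are counted.  The enhancement degree is computed and
reported but does not contribute a flag — no enhancement cut-off separates
the classes.

## Random cohort generation

`sample_cohort` draws, per histopathology class (defaults 157 normal, 17
Hashimoto, 34 non-Hashimoto lymphocytic thyroiditis, 1 diffuse
hyperplasia):

* nonenhanced and enhanced HU from untruncated normal distributions
  (normal glands 114.3 ± 21.2 / 202.5 ± 29.3 HU; DTD 94.5 ± 21.3 /
  187.6 ± 29.9 HU).  The attenuation degree is then *derived* from the HU
  draw through the banding rule, which keeps HU and degree consistent by
  construction.  The alternative — sampling the degree from the published
  frequency simplex — is incompatible with the HU distributions
  (N(114.3, 21.2) puts ~25% of normal glands below 100 HU versus the
  published 17.2%), and we chose distributional fidelity of the continuous
  measurement over the categorical marginal.
* the four remaining categorical features from per-class probability
  simplices taken from the published frequency table (e.g. lobulated
  margin 12/52 in DTD).

Features are independent by default, matching the only information the
frequency table provides (marginals).  An optional `correlation` parameter
in [0, 1] couples all features and the (inverted) HU through a single
shared latent Gaussian factor, Gaussian-copula style, because the observed
distribution of per-patient abnormal counts implies positive inter-feature
dependence.  The knob is off by default and is exercised, not calibrated.

What the generator does **not** emulate: reader variability, per-lobe
asymmetry, correlation between HU level and the visual patterns beyond the
optional latent factor, age/sex structure, and nodule-level pathology.
Tests passing on these cohorts therefore validate the arithmetic and the
pipeline, not radiologist behaviour on real images.

## Fixture reconstruction

Two deterministic 209-patient fixtures back the exact table-level checks.
The underlying study reports mutually inconsistent count breakdowns in its
confusion table and its narrative (e.g. 36 vs 31 patients with ≥ 3
abnormal features; 84 vs 54 normals with ≥ 1), so both are shipped and the
confusion table is treated as the anchor (it matches the headline
indices).

*table4 mode* fixes, per class, how many patients carry 0, 1, 2 or 3
abnormal features so that the twelve published confusion cells for
k = 1, 2, 3 hold exactly.  Counts are capped at 3 because the confusion
table does not constrain the ≥ 4 split and the narrative's split
contradicts it.

*section3 mode* realises the narrative: per-class patient counts at every
threshold 1..5 (totals 98/50/31/15/5).  The five-feature cases (n = 5,
class breakdown unstated) are assigned to Hashimoto patients, whose ≥ 4
capacity (7) admits them; an exhaustive audit over all feasible
allocations (`minimal_section3_residual`) confirms the choice attains the
minimal L1 distance to the published per-feature marginals.  Via the
sum-of-thresholds identity (Σ_k #{count ≥ k} = total abnormal instances)
the narrative forces 73 normal and 126 DTD feature instances against
marginal totals of 72 and 125 — the constraint sets are infeasible by
exactly 2, and that residual is reported by `audit_fixture`, never
silently absorbed.

Concrete features are assigned by a greedy pass: patients in descending
count order each take the features with the largest remaining demand, ties
broken by the frequency-table feature order.  This is the classic
constructive algorithm for degree-constrained bipartite realisation and
achieves every feasible marginal exactly.  When demand is exhausted (the
unavoidable +1 overflow above), the excess is assigned to the *last*
feature in table order (enhancement pattern) rather than the first, so
that the attenuation marginals — which anchor the published cut-off and
per-feature tables — survive exactly.

HU values are then drawn consistently with the flags: low-attenuation
patients from the class-conditional normal truncated below 100 HU, split
across the sub-bands (≤ 80, 80–90, 90–100) in the proportions of the
published cut-off table (8/11/8 for normals, 14/11/9 for DTD, extras to
the upper band); iso patients from the 100–180 truncation; one zero-count
normal pinned at exactly 100.0 HU.  In section3 mode one zero-count normal
additionally carries a heterogeneous attenuation pattern and one a
decreased gland, matching the non-abnormal singletons of the frequency
table.  The seed affects only the HU draws inside their bands; every
count-based quantity is seed-invariant.

## Diagnostic statistics

* **Indices.**  Plain fraction arithmetic with zero denominators flagged
  (`undefined`) instead of raised.  Display rounding is half-up to one
  decimal on percentages and four decimals on AUCs, matching the published
  tables.  Three published cells do not survive their own arithmetic and
  are documented rather than asserted: the 90-HU specificity prints 88.5
  for 138/157 (= 87.9), its PPV cell 25/43 implies TN = 139 (the row mixes
  the "< 90" and "≤ 90" conventions around a normal gland at exactly
  90 HU), and the size-normal specificity prints 14.7 for 23/157 (= 14.6).
* **AUC.**  Each published classifier is a single binary rule, so the ROC
  has one interior point and the trapezoidal area is
  (sensitivity + specificity)/2.  This reproduces the published 0.6091,
  0.7378 and 0.7566 exactly.  The other three published areas (0.6831,
  0.6238, 0.5421) equal neither this nor any arrangement of their own
  rows we could identify, and are not reproduced.  Note that the two-point
  area from the confusion table's own k = 2 row (0.7986) *exceeds* the
  k = 3 area — the published AUC column disagrees with its own counts —
  so the "best k" selection here uses accuracy (under which k = 3 wins,
  as published), while cut-off selection uses the two-point AUC (under
  which 100 HU wins, as published).
* **AUC intervals.**  Hanley–McNeil standard errors, clipped to [0, 1].
  The published 95% intervals match neither this form nor a binomial one
  and are not asserted; a patient-level bootstrap in the test suite
  confirms the Hanley–McNeil scale is right to within a factor of two for
  the binary-rule AUC.
* **Chi-square.**  Pearson, no continuity correction, empty categories
  dropped, df = (retained rows − 1) for R×2 tables.  The published size
  comparison P = 0.0749 is not reproducible under this statistic on any
  printed arrangement; the procedure behind it is unknown and it is
  excluded.
* **Logistic fit.**  Univariate maximum likelihood through statsmodels
  GLM/IRLS (max 25 iterations, tolerance 1e-8).  Complete separation is
  detected (fitted probabilities equal to the labels) and reported through
  a `converged=False` flag.

## Phantoms

Geometry: two elliptical-cylinder lobes (LR semi-axis = 0.6 × AP
semi-axis) flanking a 6 mm air trachea on a 60/90 HU soft-tissue
background; default grid 128×96×12 voxels at 0.5×0.5×3 mm (3 mm slices).
Lobe centres snap to voxel centres so an aligned AP diameter digitises
exactly; the AP extent is measured between extreme voxel centres on the
mid-lobe slice and recovers a generating diameter to within half a voxel.

Margin lobulation multiplies the boundary radius by
1 + A·sin(nθ); the sine phase leaves the AP and LR poles unperturbed, so
the generating diameter survives lobulation.  Margin classification uses
convexity deficiency (1 − area/convex-hull area, hull computed on voxel
centres so a digitised convex lobe scores exactly 0) with a default
threshold of 0.02.  Calibration on generated shapes: amplitude 0.15 with
4+ undulations exceeds the threshold; the shallower 3-undulation contour
needs amplitude 0.2.  The profile-to-phantom mapping uses A = 0.2, n = 6.

Parenchymal inhomogeneity is a Gaussian random field smoothed at 6 mm,
median-centred and normalised to unit SD per lobe, clipped at ±1.1 SD and
demeaned over the default measurement ROI.  The clip bounds the deviation
from the lobe median at 1.1 × amplitude, so a diffusely mottled gland
(mapping amplitude 40 HU) can never trip the focal-lesion rule (≥ 50 HU
over ≥ 10% of the lobe); the ROI demeaning makes the generating mean HU
exactly what the ROI reads on a noiseless phantom.  Pattern
classification is: heterogeneous if a connected region ≥ 10% of the lobe
deviates ≥ 50 HU from the lobe median; else inhomogeneous if the
within-lobe SD, after subtracting the configured sensor noise in
quadrature, exceeds 15 HU; else homogeneous.  Heterogeneous patterns are
realised as axial cylindrical lesions (−80 HU, ~14% of the cross-section)
placed posteriorly between the ROI margin and the lobe boundary.

These pattern and margin thresholds are calibrated stand-ins for a visual
reading — the study quantified neither — so no claim of agreement with a
human reader is made; what the phantoms establish is internal consistency:
on noiseless phantoms every extracted feature equals its generating ground
truth, and the imaging evaluation report equals the tabular one cell for
cell.

ROIs default to a disk of 40% of the lobe's minor semi-axis at the lobe
centre on the mid-lobe slice, keeping clear of partial-volume edge voxels;
an ROI touching the lobe boundary is a contract violation, not a warning.
On disk, HU rasters are int16 NIfTI (half-unit quantisation), masks a
uint8 label map, parameters a JSON sidecar.

## Problem sizes and numerical choices in the test suite

Sampling checks run at n = 10,000 per class with 3-standard-error bands;
chi-square equivalence is checked against the closed form on 1,000 random
2×2 tables; logistic recovery at n = 5,000 within 3 SEs; the
imaging-vs-tabular equivalence batch uses 100 patients (50 normal / 50
DTD-class) at ~150k voxels per phantom phase — sizes chosen to make
Monte-Carlo noise negligible against the tested tolerances while the whole
suite stays fast on one CPU.

## Known limitations

* The anomalous published AUCs, their confidence intervals and the size
  P value are documented, not reproduced (see above).
* The phantom emulates HU statistics and shape categories, not CT physics:
  no beam hardening, partial-volume blur, contrast kinetics or DICOM
  acquisition metadata.
* Fixture HU values are band-consistent reconstructions, not patient data;
  continuous-HU results beyond the published band counts (e.g. logistic
  coefficients) depend on the truncation model and are illustrative.
* table4-mode per-feature marginals are necessarily far from the published
  frequency table (the two published tables are mutually inconsistent at
  the instance level by 46); use section3 mode when per-feature marginals
  matter.
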