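# Methods

## Tissue classification

Each voxel inside the lung label map is assigned exactly one class by HU
thresholding:

| class | interval (HU) | interpretation |
|---|---|---|
| emphysematous | < −900 | destroyed, hyperinflated parenchyma |
| well-aerated | [−900, −501] | functional parenchyma |
| non-aerated | > −501 | poorly aerated / dense tissue |

The printed convention ("well-aerated −900 to −501", "non-aerated > −500")
leaves (−501, −500] unassigned for non-integer HU; we close the gap by
making the well-aerated band end at −501 inclusive and everything strictly
above non-aerated. For integer HU this is indistinguishable from the printed
bounds. "Functional" means the well-aerated class exactly; poorly aerated
tissue counts as non-functional. Thresholds are parameters
(`theta_emph`, `theta_well_upper`) with the constraint
`theta_emph < theta_well_upper` validated before any computation.

Volumes are voxel counts × voxel volume (mm³ → mL, i.e. /1000), stored
unrounded. Lobe/lung/whole-lung aggregates are sums of segment voxel
counts — never a re-classification — so aggregation is exact. Resection
fractions use whole-lung denominators for removed/total, removed-functional
and healthy/total; the operated side's remaining tissue for the ipsilateral
ratio; and the removed region for the removed-healthy ratio. A zero
denominator (e.g. a lung with no well-aerated tissue) raises an explicit
`UndefinedFractionError` instead of silently returning 0 or 1.

## Prediction models

* **5% rule**: `ppo = preop · (1 − 0.05·segments)`, flat 5% per segment with
  no 19-segment renormalisation. Fractional segment counts are allowed so
  cohort means can be evaluated.
* **Brunelli regressions**: exact linear evaluation of the published
  coefficient sets (FEV1: 21.34, −0.47·age, +0.49·removed functioning %,
  +17.91·COPD index; DLCO: 35.99, −0.31·age, −36.47·FEV1/FVC, +0.33·DLCO,
  +0.54·removed functioning %). Unit conventions, chosen for internal
  consistency with the reported group-level predictions: the removed
  functioning parenchyma enters on the 0–100 scale, FEV1/FVC on the 0–1
  scale (a percent-scale ratio would contribute an absurd −2500% term), and
  DLCO in measured units, mmol/(min·kPa) — %-predicted input would predict
  ~25% loss where the reported predictions sit essentially at the
  preoperative value, while measured-unit input predicts ~0.7%, which
  matches. Inputs that look like the wrong scale are rejected with a unit
  hint. Negative predicted losses (functional gain) are returned unclamped;
  only final ppo values are clamped at zero, with a warning.
* **COPD index**: the source cohort defers to Korst's definition without
  printing it; we use FEV1 %predicted (as a fraction) + FEV1/FVC, which
  reproduces the reported cohort mean exactly (0.92 + 0.69 = 1.61). The
  definition is a documented open point and the coefficients (like all
  Brunelli terms) are overridable via configuration.
* **Volumetric model**: `ppo = preop · (1 − removed functional fraction)`,
  the removed well-aerated volume over whole-lung well-aerated volume. This
  is the natural volumetric analogue of the 5% rule and the package's
  CT-driven predictor.

All three FEV1 predictors coincide when the resected region is exactly
5%-per-segment functional and the Brunelli coefficients are set to
(intercept 0, age 0, removed % 1, COPD 0) — used as a cross-model
consistency test.

## Cohort statistics

Patients are split by postoperative FEV1 response: increase means strictly
greater than the preoperative value; ties go to the decrease group (the tie
rule is configurable and documented because "showed an increase" is read
strictly). Summaries are mean with sample SD (n−1). Group comparisons use
the unpaired *pooled-variance* Student t-test (not Welch), two-sided, with
df = n₁+n₂−2; degenerate zero-variance inputs return p = 1 for equal means
and a guarded p = 0 with warning otherwise. No multiple-testing correction
is applied across compared variables. Measured-vs-predicted deviations are
reported as measured − predicted, with FEV1 in mL rounded to 10 mL for
report parity only (stored values unrounded). The pre/post relationship is
an ordinary least-squares line of postop on preop plus per-patient
identity-line residuals.

## Synthetic data

**Phantoms.** A rectangular lung envelope (grid minus a background border)
is split into a left-lung bulk region and ten right-lung axis-aligned
slabs (S1–S10; S1–S3 form the right upper lobe — the left lung is modelled
only as bulk since it serves purely as a whole-lung denominator). Each
segment draws voxel classes from its mixture weights, then HU from
class-conditional normals — well-aerated N(−750, 40), emphysematous
N(−950, 20), non-aerated N(−200, 50) — *truncated to the class intervals*.
Truncation makes the generating component exactly recoverable by
thresholding, so the emitted ground truth (realized voxel counts) agrees
exactly with the classifier; without it, tail leakage across thresholds
would make round-trip tests probabilistic. All draws flow from one seeded
generator; the seed is mandatory and identical specs give byte-identical
outputs.

**Cohorts.** Marginals emulate a 20-patient right-upper-lobe resection
series: age N(68, 10) truncated to [40, 90]; preop FEV1 N(2.48, 0.59) L
truncated above 0.8; FEV1/FVC N(0.69, 0.09) in (0.3, 0.95); DLCO
N(6.27, 1.99) above 1; RV %predicted N(118, 25); FEV1 %predicted
N(92, 15); 3/2/1 segments removed with probabilities 0.70/0.10/0.20.
Variables are drawn independently — no patient-level joint distribution is
published to emulate, and this is a stated limitation. Each resected
segment occupies N(6.88%, 1.5%) of total lung volume (truncated to
3–12%), so a mean 2.5-segment resection removes ≈17% of total lung tissue,
matching the reported resection extent for right-upper-lobe surgery. The
non-functional fraction of the resected tissue is q ~ Beta(1.8, 8.2)
(mean 0.18); the rest of the lung is h ~ N(0.90, 0.05) healthy. From these
the attached resection simulation is algebraically consistent: removed
functional fraction = r(1−q) / [(1−r)h + r(1−q)].

The outcome model is

```
postop FEV1 = preop · (1 − f_removed) · (1 + γ·q·RV%/100) + N(0, σ)
```

so losing functional tissue costs function while resecting non-functional
tissue (high q) in hyperinflated lungs (high RV%) compensates — a minimal
single-parameter stand-in for the lung-volume-reduction effect, a testing
device rather than a physiological claim. Defaults γ = 0.6 and σ = 0.15 L
were fixed once so the generated cohort reproduces the reported marginals:
mean postoperative loss ≈ 5% of baseline with a substantial minority
(~30–40%) of FEV1 gainers. Postoperative residual volume falls by a factor
(1 − 4·r·q), giving RV reductions of a few hundred mL concentrated in the
gainers; postoperative DLCO uses the same structure at half weight with
σ = 0.3 noise. With γ = σ = 0 the measured postop equals the volumetric
prediction exactly (used for parameter-recovery tests).

What a green synthetic test does **not** establish: realistic CT texture or
anatomy, respiratory-phase effects, correlated spirometric marginals, or
the true physiological magnitude of post-resection compensation.

## Numerical and design notes

* Exactness: classification partitions the lung mask by construction;
  conservation (removed + remaining = whole, per class) is exact in voxel
  counts, and exact in mL when the voxel volume is exactly representable
  (tests use 10 mm voxels = 1 mL for bit-exact checks, 1e−12 relative
  otherwise).
* The pooled t statistic is computed from the closed-form expression and
  the p-value from the t distribution; an independent library
  implementation serves as a cross-check in tests, never as the
  implementation.
* Lobe keywords (RUL → S1,S2,S3) are expanded in the I/O layer so the
  volumetric core stays nomenclature-agnostic; label tables are
  authoritative for laterality (no geometric inference).
* Pipeline runs echo every effective parameter (thresholds, coefficients,
  seed, package version) into the report's provenance block and the run
  log; exit codes are 0 (success), 2 (validation), 3 (computation).
* Known limitations: no real-CT segmentation, no %-predicted reference
  equations, no perfusion imaging, no risk/complication modelling; the
  two reported group-specific 5%-rule DLCO cells are not reproduced because
  the group-specific segment counts behind them are unpublished.
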