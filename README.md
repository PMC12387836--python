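# ppolung

Quantitative-CT lung densitometry and predicted postoperative lung function
for anatomical lung resection planning.

## The problem

Before a lobectomy or segmentectomy for lung cancer, surgeons estimate how
much lung function the patient will retain. The classical tools are crude:
the **5% rule** assumes each of the ~20 bronchopulmonary segments carries 5%
of total function, and the **Brunelli regressions** predict a percentage
loss from age, resection extent and an obstruction index. Neither accounts
for *which* tissue is removed. In emphysematous lungs the resected segments
may be largely destroyed and hyperinflated, and removing them can even
*improve* postoperative FEV1 — a lung-volume-reduction effect that
segment-counting models cannot capture.

High-resolution CT can: thresholding attenuation classifies each voxel as
well-aerated (functional, −900 to −501 HU), emphysematous (< −900 HU) or
poorly/non-aerated (> −501 HU). Aggregated over a segmental label map, this
yields the *functional* volume of a planned resection, a far better input to
prediction models than a segment count.

`ppolung` implements this pipeline end to end:

1. **`hu_volumetrics`** — HU tissue classification (a scikit-learn
   transformer), per-segment/lobe/lung class volumetrics, and
   simulated-resection fractions (removed/total, removed-functional/total-
   functional, healthy/total, ipsilateral-remaining and removed-region
   healthy ratios).
2. **`ppo_models`** — predicted postoperative values. For preoperative value
   `V`, segments removed `s`, removed functioning parenchyma `R` (%), age
   `a`, COPD index `C = FEV1%pred + FEV1/FVC`, obstruction ratio `r` and
   diffusing capacity `D` (mmol·min⁻¹·kPa⁻¹):

   * 5% rule: `ppo = V · (1 − 0.05·s)`
   * Brunelli FEV1 loss (%): `21.34 − 0.47·a + 0.49·R + 17.91·C`
   * Brunelli DLCO loss (%): `35.99 − 0.31·a − 36.47·r + 0.33·D + 0.54·R`
   * volumetric: `ppo = V · (1 − R/100)`
3. **`cohort_analysis`** — split by postoperative FEV1 response, mean (SD)
   summaries, unpaired pooled-variance Student t-tests, measured-vs-predicted
   deviations in mL, and the least-squares line of postop on preop against
   the line of no change.
4. **`synthetic_data`** — seeded CT phantoms (segment label maps with
   controlled tissue-class mixtures) and synthetic cohorts whose outcome
   model lets resection of non-functional tissue raise FEV1.
5. **`io_cli`** — NIfTI-1 + sidecar-JSON I/O, YAML configuration and the
   `ppolung` command-line pipeline.

## Worked example

Predict postoperative function for a typical right-upper-lobectomy
candidate (age 68, FEV1 2.48 L at 92% predicted, FEV1/FVC 0.69, DLCO 6.27,
3 segments removed, CT shows 16.42% of functional parenchyma in the
resection):

```python
from ppolung import predict_patient, copd_index

pred = predict_patient(
    preop_fev1_l=2.48, preop_dlco=6.27, age=68,
    fev1_pct_pred=0.92, fev1_fvc=0.69, segments_removed=3,
    removed_functional_fraction=0.1642)
print(f"COPD index:          {copd_index(0.92, 0.69):.2f}")
print(f"ppoFEV1, 5% rule:    {pred.ppo_fev1_5pct:.2f} L")
print(f"ppoFEV1, Brunelli:   {pred.ppo_fev1_brunelli:.2f} L "
      f"(predicted loss {pred.fev1_loss_brunelli_pct:.1f}%)")
print(f"ppoFEV1, volumetric: {pred.ppo_fev1_volumetric:.2f} L")
print(f"ppoDLCO, Brunelli:   {pred.ppo_dlco_brunelli:.2f} "
      f"(predicted loss {pred.dlco_loss_brunelli_pct:.1f}%)")
```

prints

```
COPD index:          1.61
ppoFEV1, 5% rule:    2.11 L
ppoFEV1, Brunelli:   1.83 L (predicted loss 26.3%)
ppoFEV1, volumetric: 2.07 L
ppoDLCO, Brunelli:   6.23 (predicted loss 0.7%)
```

The 5% rule predicts 2.11 L (three segments ⇒ 15% loss); the Brunelli
regression is far more pessimistic (26.3% loss, 1.83 L) because the COPD
index enters with a large positive coefficient; the CT-volumetric model
lands in between, and the Brunelli DLCO model predicts essentially no
diffusion loss for this profile.

The same stages run from the shell:

```bash
ppolung simulate-ct --seed 1
ppolung volumetrics --ct phantom_ct.nii.gz --labels phantom_labels.nii.gz \
    --table phantom_labels.json --plan RUL
ppolung simulate-cohort --seed 1 --n 20
ppolung predict --cohort cohort.csv
ppolung analyze --cohort cohort.csv
ppolung pipeline --seed 1 --out-dir run1   # everything, with provenance
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the published worked-example quantities by running the package on
the published cohort summary values: the cohort-mean 5%-rule and Brunelli
ppoFEV1 (from the mean preoperative FEV1, the segment-count mix and the
cohort-mean regression inputs) and the group-level measured-vs-predicted
FEV1 deviations and residual-volume reductions, all in the units and
precision in which they were reported. It also runs the full synthetic
pipeline once (seeded) so every stage executes.

## Scope and caveats

Segmental label maps are inputs: the package does not segment raw CT into
anatomical segments, emit DICOM, or compute %-predicted reference values.
Synthetic cohorts draw marginals independently and encode a deliberately
minimal compensation mechanism; see `docs/methods.md` for what green tests
do and do not establish.
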