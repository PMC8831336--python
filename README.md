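# phasebmd

Automatic detection of the intravenous-contrast phase of an abdominal CT scan,
and phase-specific correction of opportunistic trabecular bone mineral density
(BMD) measurements.

## The problem

Every abdominal CT scan contains enough information to measure the volumetric
trabecular BMD of the lumbar spine "opportunistically" — without a dedicated
osteoporosis work-up. But most abdominal scans are acquired after intravenous
iodinated contrast injection, and the contrast agent perfuses trabecular bone:
portal-venous (PV) scans overestimate BMD by roughly 13% (≈ 17.5 mg/ml) and
arterial (AR) scans by roughly 4% (≈ 5.7 mg/ml). An uncorrected PV measurement
can move a patient halfway across the gap between "normal" (BMD > 120 mg/ml)
and "osteoporosis" (BMD < 80 mg/ml). Scanner metadata rarely records the phase
reliably, so a fully automated BMD pipeline must *detect* the phase from the
image itself and then *correct* for it.

`phasebmd` implements that pipeline end to end:

1. **Anatomy-guided slice selection** — axial slices are extracted at the
   vertebral centroids of T8–L2 (up to seven slices per scan) from volumes
   resampled to 1 mm isotropic and z-score normalized, then crop-padded to
   224 × 224. A random-slice selection mode is included as a baseline.
2. **Slice-level phase classifier** — a three-class (NE / AR / PV)
   densely-connected convolutional network trained with AdamW, class-weighted
   categorical cross-entropy, label-preserving augmentation, early stopping on
   the validation macro-F1, and patient-level threefold cross-validation.
   The default `compact` backbone trains in minutes on one CPU; the classic
   161-layer bottlenecked DenseNet topology is available as `dense161`.
3. **Scan-level aggregation** — per-slice probability triples are combined by
   probability averaging (default) and by majority vote; disagreement between
   the two modes is flagged per scan.
4. **BMD extraction and correction** — mean HU over the trabecular
   compartment of each vertebra (from a multi-label segmentation mask) is
   converted to mg/ml through a scanner-specific linear calibration
   `BMD = slope · HU + intercept`, averaged over non-fractured L1–L3
   (vertebrae with fracture grade > 1 are excluded), and corrected with a
   per-phase ordinary-least-squares line `BMD_NE-equivalent = a · BMD_enhanced + b`
   fitted on training patients. The nonenhanced phase maps to identity.
5. **Evaluation** — one-vs-rest precision / sensitivity / specificity / F1 /
   ROC-AUC and accuracy for the classifier; RMSE, Bland-Altman mean difference
   and 1.96-SD limits of agreement, and a paired t-test for BMD agreement.

Because the clinical cohorts behind these numbers cannot be redistributed,
the package ships a **synthetic triphasic phantom generator**: parametric
abdominal anatomy (vertebral bodies with cortical shell and trabecular core,
aorta, liver, soft tissue) in which contrast phase appears as additive HU
enhancement per tissue — strong aortic enhancement in AR, hepatic plus
moderate aortic enhancement in PV, and trabecular offsets calibrated to induce
BMD biases of +5.68 (AR) and +17.5 mg/ml (PV). Every stage of the pipeline is
trainable and testable against exact ground truth with no external data.

## Worked example

Fit and apply the portal-venous correction on a small noiseless phantom
cohort:

```python
from phasebmd import (PhantomSpec, generate_patient, CalibrationModel,
                      fit_correction, apply_correction, lumbar_mean)
from phasebmd.bmd import extract_bmd

spec = PhantomSpec(n_patients=5, vertebral_levels=("T12", "L1", "L2", "L3"),
                   fov_size=(64, 64, 64), noise_sd=0.0, fracture_rate=0.0, seed=42)
calib = CalibrationModel(slope=spec.calib_slope, intercept=spec.calib_intercept)

lumbar = {}
for i in range(spec.n_patients):
    case = generate_patient(spec, i)
    grades = {a.level: a.fracture_grade for a in case.annotations}
    for phase in ("NE", "AR", "PV"):
        per_vertebra = extract_bmd(case.volumes[phase], case.mask, calib)
        lumbar[(i, phase)], _ = lumbar_mean(per_vertebra, grades)

pairs = [(lumbar[(i, "PV")], lumbar[(i, "NE")]) for i in range(spec.n_patients)]
model = fit_correction(pairs, "PV")
print(f"PV correction: slope={model.slope:.6f}, intercept={model.intercept:.3f} mg/ml")
bmd_pv = lumbar[(0, "PV")]
print(f"patient 0: PV-derived BMD {bmd_pv:.1f} mg/ml "
      f"-> corrected {apply_correction(bmd_pv, 'PV', {'PV': model}):.1f} mg/ml "
      f"(NE scan: {lumbar[(0, 'NE')]:.1f} mg/ml)")
```

prints

```
PV correction: slope=1.000000, intercept=-17.500 mg/ml
patient 0: PV-derived BMD 155.1 mg/ml -> corrected 137.6 mg/ml (NE scan: 137.6 mg/ml)
```

The fitted line recovers exactly the +17.5 mg/ml trabecular enhancement the
phantom injects into PV scans, and the corrected value lands on the
nonenhanced measurement.

## Command-line pipeline

The five stages run as subcommands reading one YAML config (all values have
defaults; `--seed` overrides the master seed, from which every stochastic
stage derives its own child seed):

```bash
phasebmd generate --out data/ --seed 17
phasebmd train    --data data/ --out model/ --seed 17
phasebmd predict  --data data/ --model model/checkpoint.npz --out reports/phase_predictions.csv --seed 17
phasebmd correct  --data data/ --predictions reports/phase_predictions.csv --out reports/bmd.csv --seed 17
phasebmd evaluate --data data/ --predictions reports/phase_predictions.csv \
                  --bmd reports/bmd.csv --out reports/metrics.csv --plots reports/plots --seed 17
```

On the default 30-patient phantom cohort this takes about five minutes on one
CPU and ends with a `metrics.csv` containing the scan-level classification
metrics of the held-out test split and the Bland-Altman/RMSE agreement of
AR/PV BMD against each patient's nonenhanced scan, before and after the
automated correction.

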