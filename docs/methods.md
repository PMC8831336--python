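# Methods

This note documents the models, conventions, and design choices behind
`phasebmd`: what each stage assumes, which parameters matter, what the
synthetic phantom does and does not emulate, and where the design was
genuinely open.

## 1. Synthetic triphasic phantom

### Model

Each synthetic patient is one fixed anatomy scanned in three contrast phases
(NE, AR, PV). The anatomy is parametric: stacked elliptic-cylinder vertebral
bodies (cortical shell ≈ 400 HU, trabecular core) along the cranio-caudal
axis, a tubular aorta (blood ≈ 45 HU) anterior-left of the spine, a liver
ellipsoid (≈ 60 HU) in the right upper abdomen, soft-tissue background
(≈ 40 HU) inside an elliptic body contour, air (−1000 HU) outside. Volumes
are written in RAS orientation with the axial direction along the third axis.

Contrast phase is modelled as *additive constant HU enhancement per tissue
compartment* plus i.i.d. Gaussian voxel noise:

| compartment | NE | AR | PV |
|---|---|---|---|
| aorta | 0 | +200 HU | +90 HU |
| liver | 0 | 0 | +60 HU |
| trabecular bone | 0 | +5.68/slope HU | +17.5/slope HU |

The aortic AR value is motivated by bolus tracking: the arterial scan is
triggered once an aortic ROI exceeds 120 HU, so realized aortic enhancement is
well above that threshold. The PV aortic and hepatic values are *plausible*
portal-venous levels, not measured ones — no published quantity pins them
down, and the classifier only needs them to be phase-discriminative. The
trabecular offsets are chosen so that the induced *BMD* bias through the
HU→BMD calibration equals the biases measured on real triphasic abdominal
MDCT: +5.68 mg/ml (AR) and +17.5 mg/ml (PV). The additive-enhancement model
is deliberately matched to the linear-correction assumption of the BMD stage,
which makes parameter recovery well-posed and exactly checkable.

### Parameters (defaults)

| parameter | default | unit | why |
|---|---|---|---|
| `n_patients` | 30 | — | desk-scale cohort; 90 scans |
| `vertebral_levels` | T8…L4 | — | covers the classifier input (T8–L2) and the BMD levels (L1–L3) |
| `bmd_mean`, `bmd_sd` | 130, 35 | mg/ml | typical abdominal-CT cohort (nonenhanced mean ≈ 132 mg/ml) |
| `calib_slope`, `calib_intercept` | 0.8, 0.0 | mg/ml per HU, mg/ml | representative QCT phantom calibration; real coefficients are scanner-specific config |
| `enh_aorta_ar` | +200 | HU | above the 120 HU trigger |
| `enh_aorta_pv`, `enh_liver_pv` | +90, +60 | HU | plausible portal-venous levels (see above) |
| `noise_sd` | 20 | HU | moderate abdominal-CT noise |
| `voxel_spacing` | 2 mm iso | mm | training speed; 1 mm available via config |
| `fov_size` | 96×96×(16·levels) | voxels | one 32-mm band per vertebral level |
| `fracture_rate` | 0.1 | — | between the training (0.21) and test (0.09) fracture prevalences of real cohorts |

Fractured vertebrae get a height-reduction deformation (22.5% / 32.5% / 45%
for grades 1–3, the midpoints of the semiquantitative grading bands) and the
grade is recorded in the annotation; grading itself is an *input* to this
package, never computed from the image.

Determinism: all randomness (BMD draws, fracture assignment, voxel noise)
derives from `SeedSequence([seed, patient_index, stream])`, so a fixed spec
regenerates byte-identical volumes.

### What the phantom does not emulate

No CT physics (beam hardening, scatter, kernel-dependent noise texture), no
respiratory or positioning variation, no oral contrast, no perfusion
heterogeneity within a tissue, no inter-scanner domain shift. Consequently,
passing phantom tests demonstrates that the *pipeline logic* is correct —
slice selection, training protocol, aggregation, calibration, correction,
statistics — not that the classifier would reach the same accuracy on
clinical data.

## 2. Preprocessing

Fixed order, part of the contract: resample the whole volume to isotropic
spacing (linear interpolation; grid size `round(size·spacing/target)`, which
preserves physical extent to within one voxel) → z-score normalize the whole
volume (population-SD convention) → extract axial slices → crop-pad each
slice to 224 × 224.

Open choices resolved here:

* **Normalization scope** — whole volume before slicing, so inter-slice
  contrast relationships survive; per-slice normalization would erase part of
  the enhancement signal.
* **Slice selection** — the axial index nearest the centroid's world z; an
  exact half-voxel tie breaks toward the caudal slice. Requested levels
  missing from the annotations or outside the volume are silently skipped
  (aggregation later uses all available predictions); zero available levels
  is an error.
* **Crop center** — the centroid's in-plane position for anatomy-guided
  slices (keeps aorta and vertebra in frame on large fields of view), image
  center for random slices. Padding uses the image minimum (air-equivalent
  after normalization).

## 3. Slice classifier

### Backbones

`compact` (default): 4× average pool → 3×3 conv (16 ch) → 2× pool → three
dense blocks (two 3×3 layers each, growth 12) with 1×1-conv transitions →
**flattened 7×7 spatial map → linear**, ≈ 25 k parameters. The flatten head
(rather than global average pooling) is deliberate: anatomy-guided crops are
centered on the vertebral centroid, so the phase evidence is *positional* —
aortic enhancement anterior-left of the spine, hepatic enhancement on the
right. Global pooling destroys that information; empirically the same trunk
with a GAP head stays at chance while a flattened head separates the phases
quickly.

`dense161`: the canonical 161-layer bottlenecked densely-connected topology
(96-channel stem, blocks 6/12/36/24, growth 48, GAP head), constructible and
runnable for completeness, without batch normalization or pretrained weights;
training it is not practical on CPU.

### Training protocol

AdamW, class-weighted categorical cross-entropy (weights = inverse class
frequency normalized to mean 1, so balanced data reduces to the unweighted
loss), early stopping monitored on validation **macro-F1** with the best
checkpoint returned, and patient-level folds (`k = 3` by default; all scans
of a patient share its fold, so phases of one anatomy never straddle splits).
Early-stop semantics: training stops once `epoch − best_epoch ≥ patience`;
patience 0 therefore trains exactly one epoch.

Two default sets exist on purpose:

* `TrainConfig` class defaults — batch 100, lr 1e-4, full augmentation set
  (flips, rotation, zoom, random crop, random field of view). These suit
  fine-tuning a large pretrained backbone.
* Pipeline defaults (`PipelineConfig.train`) — batch 50, lr 3e-3, 80 epochs,
  patience 30, augmentation restricted to rotation (±10°) and zoom
  (0.9–1.1×). A small network trained from scratch needs larger and more
  frequent steps, and flip/crop/FOV transforms destroy exactly the
  left-right and position cues the compact head uses (mirroring swaps the
  aorta and liver sides, which is anatomically impossible in RAS-oriented
  scans). With these defaults validation F1 reaches 1.0 on phantom cohorts
  in ≈ 40 epochs on one CPU.

All augmentation transforms are label-preserving and seeded; "random field of
view" is interpreted as window-crop-then-resize, the name being otherwise
underspecified.

## 4. Aggregation

Both aggregators are implemented and always computed; the report flags scans
where they disagree.

* `mean` (default): average the per-slice probability triples, call the
  argmax. Smoother, and uses the full probability information.
* `majority`: per-slice argmax first, then the modal class; vote ties break
  by the higher mean probability, remaining exact ties by the fixed class
  order NE < AR < PV (the same order breaks argmax ties everywhere).

Both are invariant to slice order, and agree whenever every slice's argmax
agrees.

## 5. BMD extraction and correction

* Trabecular mean HU per vertebra from the mask's trabecular subregion codes
  (vertebra label + 100), converted by the scanner calibration
  `BMD = slope·HU + intercept`. Calibration coefficients are config inputs;
  the phantom supplies known ones for testing.
* Lumbar BMD = unweighted mean over included L1–L3. A vertebra is excluded
  when missing from the mask or when its fracture grade exceeds the threshold
  (default `exclude_grade_above = 1`, i.e. grades 2–3 excluded; the stricter
  "exclude all fractured" variant is a config switch because the literal
  grading convention is ambiguous at grade 1). Ungraded vertebrae are
  included. Exclusions are itemized per scan, and a scan with nothing left is
  reported as a coverage error, never silently dropped.
* Correction: per enhanced phase, an OLS line *predicting the NE-equivalent
  BMD from the enhanced BMD* — the predictive direction is the one usable at
  inference time, when no NE scan exists. Fitted on training patients with
  known phases (≥ 3 pairs; degenerate abscissae are an error); residual SD is
  reported with the model. A constant-offset variant (slope pinned to 1) is
  available. At inference the *predicted* phase selects the line; NE is the
  identity.

On noiseless phantoms the full round trip (extract → calibrate → correct) is
exact: fitted slope 1, intercept = −bias, corrected BMD = ground truth to
better than 1e-6 mg/ml. This requires keeping in-memory phantom volumes in
float64; volumes read from disk are float32, the working precision of the
imaging path.

## 6. Evaluation statistics

* Classification: one-vs-rest per class; specificity = TN/(TN+FP) with the
  rest pooled; averages are macro over classes present in the truth (the
  averaging mode is config-exposed since Table-style summaries can be defined
  either way). AUC is the rank statistic (ties count ½), per class vs rest;
  a class absent from the truth has undefined AUC, reported as missing and
  skipped by the average.
* Agreement: differences are test − reference; RMSE; Bland-Altman limits use
  the sample-SD (n−1) convention, mean ± 1.96·SD; two-sided paired t-test
  with df = n−1. Zero-variance differences are flagged degenerate (p = 1 when
  the mean is also 0). RMSE ≥ |mean difference| always holds.

## 7. Pipeline, seeds, problem sizes

One YAML config drives the five CLI stages. The master seed is never used
directly: each stochastic stage (phantom, split, training, random slice
selection) consumes a fixed-offset child of it, so stages are independently
reproducible and two runs under one seed produce byte-identical report CSVs.

Default problem sizes: 30 patients × 3 phases; patient-level 75/25
train/test split; threefold cross-validation inside the training split with
fold 0 held out for early stopping; 7 slices per scan at 224 × 224 after
1-mm resampling. The full pipeline runs in about five minutes on one CPU;
noiseless parameter-recovery cohorts (6 patients, no noise, no fractures)
run in seconds.

## 8. Known limitations

* The phantom's geometric simplicity means classifier accuracy on it says
  nothing quantitative about clinical accuracy; only directions and
  mechanisms transfer.
* The compact backbone's flatten head assumes anatomy-centered crops; for
  uncentered inputs (e.g. the random-slice baseline on heterogeneous fields
  of view) a pooled head or the `dense161` option is the better choice.
* Annotation sidecars are read in world millimetres only; datasets that store
  centroids in voxel indices need a conversion step upstream.
* The correction is a global per-phase line; patient-specific factors
  (diameter, positioning, injection timing) are out of scope, as is internal
  (in-body) calibration.
* 3-D volumetric classification is a config stub only (`dense161` covers the
  documented 2-D full-scale topology; a 3-D variant needs accelerator
  memory).
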