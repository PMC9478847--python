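# Methods

## The problem and the model

`phenomap` implements a hyperspectral-imaging chemometrics workflow for
non-destructive prediction of total phenolic content (mg per g dry
weight) in small rosette plants such as Arabidopsis. The measurement
chain is:

1. **Reflectance calibration.** Raw line-scan counts `I_h` are converted
   to relative reflectance with white/dark references,
   `I_c = (I_h − I_d)/(I_w − I_d)`. Reference frames are averaged over
   acquisition lines before the correction to suppress shot noise, and
   reflectance is clipped to [0, 1.5] with the clipped-voxel count
   logged (the handling of out-of-range voxels is an implementation
   choice; the correction itself is silent on them).
2. **Segmentation.** The canopy is separated from soil and pot using
   three named wavelengths (947/1,535/1,946 nm in the SWIR,
   560/655/750 nm in the VIS/NIR). The classifier is deliberately
   parameter-light: a normalized difference between a vegetation-bright
   and a background-bright channel, Otsu-thresholded, largest connected
   component kept, small holes filled. A minimum absolute foreground
   score (default 0.1) rejects scenes with no vegetation present.
3. **Dataset assembly.** Each plant mask is divided into k = 10 random
   regions and each region's mean spectrum becomes one modelling row
   (10 × 120 plants = 1,200 rows). "Random regions" is realised as
   seeded k-means on pixel coordinates, giving spatially coherent
   patches that capture within-plant physical variation; a
   pure-random-assignment variant is available (`method="random"`).
   Rows carry their growing condition's group-level reference total —
   the pooled-sample quantification means every plant of a condition
   shares one reference value. Wavelengths are trimmed to 400–990 nm
   (VIS/NIR) or 920–1,970 nm (SWIR) before modelling; the excluded
   edges are noise-dominated. The dataset is split 70:30 into
   calibration and validation at the spectrum level by default; a
   plant-level split is provided because spectrum-level splitting lets
   regions of one plant appear on both sides (documented caveat, not
   the default).
4. **Pretreatment.** Eight row-wise options: none, mean/max/range
   normalization, MSC, SNV, and Savitzky–Golay first/second
   derivatives. MSC's reference is frozen as the calibration-set mean
   (standard chemometric convention); validation rows are never
   corrected against their own batch. SG defaults are window 11,
   polyorder 2 (first derivative) or 3 (second); derivatives are per
   band index, which on the uniform trimmed grids differs from per-nm
   only by a constant to which the subsequent bilinear regression is
   equivariant.
5. **Calibration.** Univariate PLSR fitted by NIPALS in score/loading
   form (X = AB′ + C, Y = DE′ + F, inner relation D = AG + H), X
   centered but not variance-scaled (scale handling is the
   pretreatment's job). The latent-variable count is chosen by 5-fold
   cross-validation with the one-standard-error rule — the smallest
   count whose CV RMSE is within one SE of the minimum — since the
   reference study does not report its count or scheme; the selection
   policy is recorded in every output. Figures of merit: R², SEC with
   n − a − 1 degrees of freedom on calibration, bias-corrected SEP on
   validation, plain RMSE and bias alongside.
6. **Waveband reduction.** For each band, the across-sample vector of
   calibration values (fixed dataset order, serialized with the
   selection) is DCT-II transformed; the DC coefficient and the upper
   half of the AC frequencies are discarded and the band is scored by
   its largest absolute retained coefficient. Peaks of the score curve
   (prominence ≥ 5 % of the score range, separation ≥ 1 band, endpoints
   eligible, plateaus resolved to their left edge) are the reduced
   waveband set. The transform axis, the 50 % high-frequency cut and
   the peak criterion are configuration, not asserted properties of the
   original method, which leaves all three open; the per-spectrum
   transform axis is available for comparison (`axis="spectrum"`).
7. **Chemical imaging.** The fitted regression vector is applied at
   every mask pixel after the exact training pretreatment,
   `map = (preprocess(x) − mean_x)·K·L + intercept`. The scale constant
   L defaults to 1 and is never serialized into predictions, and the
   centering/intercept are always included so the map stays in mg/g.
   For linear pretreatments (raw, SG derivatives) the mask-mean of the
   map equals the prediction from the mask-mean spectrum; for nonlinear
   ones (SNV, MSC, range normalization) this identity does not hold and
   the divergence is reported rather than asserted.

## Synthetic scenes

No imagery is distributed with the original study, so the package
generates its own scenes with known ground truth. A plant pixel's
latent reflectance is

    a · (baseline − c · signature) + b,

where `baseline` is a smooth vegetation spectrum (water absorption dips
near 1,450 and 1,940 nm in the SWIR; green bump, chlorophyll dip and
red edge in the VIS/NIR), `signature` is a non-negative Gaussian-sum
absorption profile whose maxima sit in the C–H overtone windows
associated with phenolic compounds (1,110–1,130 and 1,645–1,670 nm in
the SWIR; 450–475 and 535–565 nm in the VIS/NIR), `c` is the plant's
total phenolic concentration, and `a ~ N(1, 0.02)`, `b ~ N(0, 0.005)`
are per-pixel multiplicative/additive scatter — exactly the distortion
family MSC and SNV are designed to remove, so the pretreatment
comparison is meaningful. Raw counts are `dark + latent·(white − dark)`
plus Gaussian sensor noise (default SD 0.01). The canopy is a rosette
of overlapping disks so the region partition is non-trivial.

Key generator constants, chosen once as the desk-scale study
conditions:

| parameter | default | why |
| --- | --- | --- |
| cohort layout | 8 conditions × 15 plants | the study's 120-plant design |
| condition means | packaged compound-table totals, 0.977–2.194 mg/g | ties the dynamic range to the published reference table |
| per-plant SD | 0.05 mg/g | within-condition variability is unreported; 0.05 is small against the 1.2 mg/g between-condition span and comparable to the smaller published group SDs |
| signature depth | 0.09 reflectance per mg/g | puts the concentration signal (~0.11 reflectance across the cohort range) well above scatter/noise while keeping reflectance positive |
| scene size | 64 × 64 px, 106 bands (920–1,970 nm, 10 nm) | smallest geometry at which segmentation, 10-region partition and band selection are all non-trivial |
| noise SD | 0.01 | visible in spectra but not limiting |

The reference table records the **condition mean**, not the per-plant
truth (mirroring pooled group-level quantification); per-plant truths
are retained separately for recovery tests. Scenes are realised lazily
so a 120-plant cohort never holds more than one cube in memory.

What the generator does *not* emulate: radiative-transfer leaf optics,
line-scan geometric distortion, soil/pot texture, illumination
non-uniformity, or per-plant reference values. Passing tests therefore
demonstrate that the pipeline recovers a planted, additive-absorption
signal under affine scatter and Gaussian noise — not that it would
reach the same figures on real imagery.

## Numerical choices and degenerate inputs

- ENVI I/O supports interleaves bsq/bil/bip, float32 and uint16,
  little-endian — a minimal interoperable subset, written in-repo since
  no ENVI reader ships with the environment. Round trips are bit-exact.
- Band lookup is nearest-neighbour with ties broken to the lower
  wavelength; targets beyond the grid by more than half a band spacing
  are errors.
- The calibration denominator is guarded by ε = 1e-9; coincident
  white/dark references raise rather than producing infinities.
- Constant spectra make SNV/range-normalization undefined: these raise
  a degenerate-spectrum error at the dataset level and flag the pixel
  (sentinel value, logged) at the chemical-imaging level.
- NIPALS stops with a rank error when the X′y covariance vanishes;
  cross-validated selection backs off to the achievable rank per fold
  and extends the CV curve flat beyond it.
- k-means region partitions use 4 restarts under a fixed seed; the
  labelling is deterministic given (mask, k, seed).
- All randomness flows through explicit integer seeds; a pipeline run
  derives stage seeds from the config seed, and repeat runs agree to
  the last bit (audited by test and acceptance script).

## Known limitations

- Group-level references bound the achievable calibration: the model
  is trained against condition means, so per-plant recovery inherits
  the within-condition SD as an error floor.
- The segmentation score assumes one plant per scene; multi-plant
  instance separation is out of scope.
- Baseline comparator models (SVM, regression tree) are not in the
  package; the PLSR-vs-alternatives comparison can be reproduced with
  scikit-learn estimators on the exported spectra table, and only the
  in-repo estimator is tested here.
- The reduced-waveband count depends on the peak-picking configuration;
  no particular count (e.g. the published 35) is asserted, because the
  transform axis, AC cut and peak criterion are not specified by the
  original description and the imagery is unavailable.
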