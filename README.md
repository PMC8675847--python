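# dectquant

Quantification of gold-nanoparticle (AuNP) contrast agent from dual-energy
computed tomography (DECT), for preclinical imaging groups who want
voxelwise Au concentration maps and organ-level biodistribution without
dissecting the animal for ICP-MS.

Two CT acquisitions at different tube potentials (80 and 140 kVp) respond
differently to a high-Z material — gold's k-edge at 80.7 keV makes its
attenuation strongly energy-dependent, while soft tissue's barely changes.
Each voxel's pair of CT numbers therefore determines two unknowns, the
water and gold concentrations, through a linear two-material model:

```
[C_w ]   [ e_w,80   e_Au,80  ]^-1  [ CT'_80  - b_80  ]
[C_Au] = [ e_w,140  e_Au,140 ]     [ CT'_140 - b_140 ]
```

with concentrations in mg/ml and sensitivities *e* in HU'·ml/mg.  The gold
sensitivities (slopes of CT number vs concentration) are calibrated by
ordinary least squares from a five-vial phantom (250–2000 μg/ml Au); the
water column is pinned by the shifted-CT convention CT' = HU + 1000, under
which water contributes exactly 1 HU' per mg/ml and the 2×2 matrix is
invertible whenever e_Au differs between energies.  The package covers:

- **synthetic data** — digital five-vial PMMA calibration phantom and an
  ellipsoid-organ mouse volume (tumour, kidneys, lungs, spleen, heart,
  liver) with known ground-truth concentration maps, forward-projected with
  per-energy Gaussian noise;
- **calibration** — `DualEnergyCalibration(...).fit()` →
  `CalibrationResults` with the sensitivity matrix, r², condition number
  and a back-prediction validation against reference concentrations;
- **decomposition** — `MaterialDecomposition(image, sensitivity).fit()` →
  per-voxel closed-form inversion into water/gold maps with diagnostics
  (negative-voxel fraction, condition number);
- **quantification** — organ ROI means vs reference (ICP-MS-style) values:
  relative errors, Pearson correlation, bias, and the targeted vs
  non-targeted tumour uptake ratio;
- **haemolysis** — the normalized 540 nm absorbance statistic
  `(abs_sample − abs_neg) / (abs_pos − abs_neg)` for nanoparticle
  haemocompatibility assays;
- a `dectquant` CLI tying the stages into a reproducible pipeline with a
  checksummed manifest (NIfTI volumes, CSV/JSON tables, YAML configs).

## Worked example

Noiseless phantom calibration and round-trip (the numbers below are the
script's actual output):

```python
import dectquant as dq

maps = dq.build_phantom(dq.PhantomSpec())
labels = dq.vial_label_volume(dq.PhantomSpec())
img = dq.forward_project(maps, protocol=dq.ScanProtocol(noise_sd=0.0, seed=1))
cal = dq.DualEnergyCalibration.from_image(img, labels, (250, 500, 1000, 1500, 2000)).fit()
print(cal.summary())
```

```
Dual-energy sensitivity calibration
===================================
  energy      e_w     e_Au  intercept      r^2
     low   1.0000  22.0000    1000.00  1.00000
    high   1.0000  27.0000    1000.00  1.00000
condition number: 242.996
units: sensitivities HU'/(mg/ml); intercepts HU' (CT = HU + 1000)
```

The fitted slopes are the generating gold sensitivities (22 and 27
HU'·ml/mg), the intercept is the water baseline, and r² = 1 because the
data are noiseless.  Decomposing the same image and validating against the
nominal vial list recovers every concentration exactly:

```python
res = dq.MaterialDecomposition(img, cal.sensitivity, mask=maps.mask).fit()
print(cal.validate([250, 500, 1000, 1500, 2000]).to_string(index=False))
```

```
 reference_ug_ml  recovered_ug_ml  relative_error
           250.0            250.0             0.0
           ...
          2000.0           2000.0             0.0
```

The full pipeline (simulate → calibrate → decompose → quantify, mouse legs
for both probes, 5 HU noise) prints, among other diagnostics:

```
"quantification_nontargeted": { "correlation": 0.9992, "mean_abs_relative_error": 0.0403 }
"tumour_uptake_ratio": 2.0938
```

i.e. organ DECT means correlate at r ≈ 0.999 with the ground-truth
(reference) concentrations, and the folate-targeted probe shows ≈2×
tumour uptake — the generating ratio — recovered from the noisy images.
Run it yourself with `dectquant run --out demo --seed 1`.

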