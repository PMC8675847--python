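# Methods

## The two-material model

A reconstructed CT number is, to good approximation, linear in the
concentrations of the materials occupying the voxel.  At tube potential E
we model the *shifted* CT number CT' = HU + 1000 as

    CT'_E = b_E + e_w,E · C_w + e_Au,E · C_Au,

with C_w, C_Au in mg/ml and the sensitivities e in HU'·ml/mg.  Working in
HU' rather than HU is essential: in true Hounsfield units water is 0 HU at
every energy, so the water sensitivity would be 0 and the 2×2 system
singular.  On the shifted scale air is 0, water is 1000, and the water
sensitivity is exactly 1 HU'·ml/mg for water at its physical density of
1000 mg/ml.  The shift is image metadata; it is applied and removed only
at I/O boundaries (NIfTI files store true HU).

Given the two measurements per voxel, the concentrations are the unique
solution of the intercept-subtracted 2×2 linear system.  The solver is the
closed-form inverse — no iteration, no regularisation — with degeneracy
policed by a single condition-number cap (default 1e8, i.e. only rejecting
systems that are numerically singular in 64-bit arithmetic; the default
matrices sit near cond ≈ 250, which is benign).  The analytic inverse is
tested against a generic linear solver on random well-conditioned systems
to 1e-9 relative agreement.

Assumptions inherited from this model: the pipeline is post-reconstruction
(no projection-domain physics), the response is affine in concentration
over the calibrated range, the two volumes are co-registered, and exactly
two materials explain each voxel.

## Calibration

The gold sensitivities are the per-energy OLS slopes of vial ROI mean CT'
against nominal Au concentration from a five-vial phantom (250, 500, 1000,
1500, 2000 μg/ml).  The fitted intercept absorbs the diluent/background
baseline and is subtracted before decomposition, so a constant offset in
the scanner's calibration cannot leak into the gold map.  Unweighted OLS
is the default (the calibration procedure is a plain linear correlation);
1/sd² inverse-variance weighting is available as a flag and coincides with
OLS when vial noise is homoscedastic.  The water sensitivities are fixed
at the convention value rather than fitted; a water-dilution series can
override them via `fit_sensitivity(..., e_water=...)`.  A negative fitted
slope is flagged with a warning, not an error — it indicates a broken
series, and the user should see the fit rather than a crash.

Calibration quality is reported as per-energy r², the 2×2 condition
number, and a round-trip validation that back-predicts each vial's
concentration from its mean CT' pair (per-vial relative error, Pearson
correlation against the reference list).

## Default sensitivity coefficients

The defaults are e_Au,80 = 22 and e_Au,140 = 27 HU'·ml/mg.  Reported
hepatic HU elevations for gold at these two potentials (≈22 HU at 80 kVp
and ≈27 HU at 140 kVp per unit concentration) anchor the magnitudes, and
the ordering e_Au,140 > e_Au,80 reflects gold's 80.7 keV k-edge: much of a
140 kVp spectrum lies above it, so the high-energy scan is *more*
sensitive to gold — the opposite of iodine, and the physical basis of the
decomposition's leverage.  These are configuration values
(`options.sensitivity` in the pipeline config); no algorithm hard-codes
them.

## Noise model and propagation

Noise is additive, independent, Gaussian per voxel per energy, applied to
reconstructed voxels; dose parameters (mAs 250, pitch 1) are carried as
protocol metadata only and influence nothing but the user's choice of
`noise_sd`.  The default is 5 HU at both energies, a plausible
soft-tissue noise level for a high-dose (250 mAs) abdominal protocol.

Because the solve is linear, per-voxel noise propagates in closed form:
with i.i.d. HU' noise of sd σ at both energies, the recovered gold
concentration has sd σ·‖second row of M⁻¹‖₂.  For the default matrix this
is ≈0.283·σ mg/ml per voxel — individual voxels are noisy, which is why
all reported quantities are ROI means, whose standard error shrinks as
1/√n.  The empirical sd matches the closed form within 5% on ≥10⁵ voxels,
negative voxels appear at the expected rate, and ROI means are unbiased.
Negative recovered concentrations are retained by default precisely to
keep ROI means unbiased; clipping at zero is available for display and is
applied after the negative-voxel fraction is recorded.

## Synthetic objects and what they do (not) emulate

**Calibration phantom** — a 30 mm-radius cylinder (PMMA-equivalent
background, 1120 mg/ml water-equivalent ≈ +120 HU) with five 4 mm-radius
vials on a ring, each an aqueous Au suspension at one of the five nominal
concentrations; grid 72×72×8 at 1×1×0.625 mm (~400 voxels per vial).  The
vial size/spacing and the PMMA water-equivalent are package defaults, not
measurements of any physical phantom.

**Mouse volume** — an ellipsoidal trunk (semi-axes 14×10×20 mm) with
ellipsoidal organs painted in a fixed priority order; the tumour is a
0.1 cm³ flank sphere, the mean tumour volume at the imaging time point.
Grid 80×60×72 at 0.4×0.4×0.625 mm (hospital-CT in-plane resolution and
slice thickness), giving ~1000 tumour voxels.  Default non-targeted organ
concentrations (μg/ml): liver 3000, spleen 2500, kidneys 1000 each, lungs
600, heart 500, tumour 1500 — a reticuloendothelial-dominated pattern
plausible 3 h after intravenous injection of a 3×10³ μg/ml dose.  The
folate-targeted probe multiplies tumour concentration by the scenario's
targeting ratio (default 2, the reported targeted/non-targeted contrast).
Lungs carry a low water-equivalent (300 mg/ml) to mimic aerated tissue.

The generator shares the decomposition's linear forward model, so passing
round-trip tests demonstrates correct inversion, calibration and
bookkeeping — not robustness to beam hardening, scatter, partial-volume
blur, motion, or mis-registration, none of which are simulated.  Organ
boundaries are voxel-sharp; real ROI statistics would include
partial-volume contamination.

**Reference (ICP-MS-style) values** are the scenario's ground-truth
voxel-mean concentrations; tissue-mass weighting is approximated by
voxel-volume weighting.  An optional multiplicative lognormal perturbation
(`perturb_reference`) emulates reference-assay error; it is off by
default, treating the reference as gold standard.

## Haemolysis statistic

For 540 nm absorbances, haemolysis = (abs_sample − abs_negative) /
(abs_positive − abs_negative), computed per replicate against the mean
controls and summarised by mean and sd over replicates (triplicates in the
default fixture, which mirrors the 200–600 μM assay grid).  The statistic
is invariant to adding a constant to all absorbances and to positive
rescaling; an assay whose positive control does not exceed its negative
control is rejected as invalid.  Fractions below zero (sample reading
under the negative control) are reported as computed and flagged, never
clipped.  The positive control is conventionally water-lysed blood; only
the label matters to the computation.

## Pipeline and reproducibility

`run_pipeline` executes simulate → calibrate → decompose → quantify from
one validated config (pydantic schema; unknown fields are rejected with
the offending field path).  One master seed is split into per-stage
substreams via `numpy.random.SeedSequence`, so a rerun with the same
config and seed is bit-identical; the manifest records package version,
seed, config hash, per-stage results and a SHA-256 for every output file.
Uncompressed NIfTI is used so checksums are content-deterministic.

## Numerical choices and edge cases

- Units: external surfaces (CSV, NIfTI maps, configs) are μg/ml; internal
  math is mg/ml; the factor 1000 is applied exactly once each way.
- Geometry: 0-based voxel-centre coordinates with physical spacing in mm;
  vials are axis-aligned cylinders, organs axis-aligned ellipsoids.
- A calibration series with fewer than two distinct concentrations is a
  degenerate design (error); equal slopes at both energies yield an
  infinite condition number and are refused by the decomposition cap.
- ROI statistics use the sample sd (ddof=1), reported as 0 for single-voxel
  ROIs; relative error is defined only for positive reference values, with
  the absolute difference reported otherwise; Pearson correlation is
  reported as undefined for fewer than two organs or zero variance.
- No volume-conservation constraint links C_w and C_Au; the model treats
  them as independent unknowns.

## Problem sizes

Defaults were chosen so every simulation in the test suite and the
acceptance script runs in seconds on one CPU: phantom ~41k voxels, mouse
~345k voxels, noise-propagation checks on 1.25×10⁵-voxel uniform blocks,
seed-averaged bias checks over 10 replicates of 3.3×10⁴ voxels.

## Known limitations

- Two materials, two energies only; no k-edge three-bin or multi-material
  decomposition.
- Image-domain only: quantitative accuracy on real scanners depends on
  beam-hardening correction and cross-energy registration upstream.
- The ellipsoid mouse is a geometric cartoon; it validates the estimator,
  not segmentation (organ labels are inputs throughout).
- Haemolysis handles single-wavelength readings only.
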