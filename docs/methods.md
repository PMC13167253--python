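# Methods

## The calibration model

CT numbers depend on the effective energy of the beam. A spectrally
shaped low-dose chest protocol (silver filter; "LDCT") has a harder beam
than a copper-filtered, ECG-gated calcium-scoring protocol ("CSCT"), so
the same material reads lower HU on LDCT — increasingly so for
high-atomic-number materials like calcium hydroxyapatite. `cacalib`
models the relationship as a polynomial

    I_CSCT = c_k · I_LDCT^k + … + c1 · I_LDCT + c0

fitted by ordinary least squares to paired mean HU values measured in
2-cm circular ROIs at the centers of tissue- and bone-equivalent rod
inserts of electron-density phantoms scanned with both protocols.

Fit details:

* The abscissa is affinely mapped onto [−1, 1] before building the
  Vandermonde design matrix; the fitted coefficients are composed back to
  the raw-HU basis, and both representations evaluate identically within
  1e-9 relative. This keeps order-3 and order-4 designs on HU ranges of
  several thousand numerically benign.
* Candidate orders (default 1–3) are each fitted; an order is excluded as
  badly conditioned when the scaled design matrix is rank deficient or
  its condition number exceeds 1e8. Among the remaining orders the
  minimum-SSE fit is selected. SSEs within 1e-10·max(SStot, 1) of the
  minimum are treated as tied and resolve to the lower order, so data that
  is exactly linear selects a line rather than whichever higher order wins
  by rounding dust. An explicit order override is available.
* r² is reported as 1 − SSE/SStot with SStot about the mean of the
  reference HU values, alongside SSE, per candidate order.
* The built-in reference mapping is the cubic with coefficients
  (3.871e-7, −8.504e-4, 1.453, −12.97), highest degree first. Its
  derivative 3c3·x² + 2c2·x + c1 has discriminant
  (1.7008e-3)² − 4·1.1613e-6·1.453 < 0, so the cubic is strictly
  increasing on the whole HU axis and is safe to invert and to
  extrapolate.
* Applying a curve is a pure voxel-wise polynomial evaluation; geometry,
  masks and metadata are untouched, and the protocol tag moves
  LDCT → cLDCT (only LDCT volumes may be calibrated). Evaluation outside
  the fitted domain is allowed but logged — lung and air voxels must map
  smoothly even though no insert samples that region; no clamping is
  applied.
* Curve inversion (needed by the simulator, and exposed as
  `invert_curve`) is elementwise bisection on [−3000, 5000] to a bracket
  width of 1e-6 HU, vectorized so whole volumes invert in a few dozen
  array passes. Bisection was preferred over closed-form cubic roots so
  any monotone user-supplied transfer works unchanged.

## Calcium scoring

Scoring implements the planimetric Agatston convention: per slice and per
artery label, 8-connected components of voxels ≥ 130 HU with at least 3
pixels; lesion score = pixel area (mm²) × weight, with half-open weight
bins [130, 200) → 1, [200, 300) → 2, [300, 400) → 3, [400, ∞) → 4 so that
integer HU reproduce the conventional 130–199/200–299/300–399/>399
labels. The volume score is voxel volume × calcified-pixel count. Totals
are exact sums over RCA, LAD, LCX and LM. The per-lesion weight uses the
lesion's per-slice peak HU, consistent with the per-slice score
definition. A 3-D 26-connected mode exists for sensitivity analyses.
Scoring at slice thicknesses other than 3 mm warns (the Agatston score is
defined at 3 mm); no thickness renormalization is applied since both
emulated protocols reconstruct at 3 mm. Artery masks are inputs — the
package does not segment coronaries — and lesions cannot span two labels
because the component search is masked per label.

The threshold is always re-applied to the volume being scored, so on
cLDCT the 130-HU cut acts on calibrated values. Since the calibration
maps LDCT 130 to ≈ 162 on the reference scale, near-threshold calcium
that is invisible on raw LDCT is recovered on cLDCT.

## Agreement statistics

Pairwise protocol agreement uses OLS regression with r² (squared
Pearson), and Bland-Altman bias = mean(B − A) with 95% limits of
agreement bias ± z(1−α/2)·SD(B − A), SD with the n−1 denominator and
z(0.975) = 1.959964. LoA are also reported as a half-width ("bias ±
LoA"). Per-artery score comparisons use a two-sample t-test — Welch with
Satterthwaite degrees of freedom by default, since score variances differ
strongly between protocols; the pooled variant is selectable. Tests are
two-sided at α = 0.05 with no multiple-testing correction. The unpaired
test is applied to paired per-patient scores deliberately, mirroring
common practice in protocol-comparison studies; a paired test would be
more powerful but is not the default. Cohorts are stratified into four
heart-rate subgroups (diastolic < 60, 60–65, > 65 bpm; systolic), with a
pluggable rule.

## The synthetic-data generator

The simulator exists so that every stage can be validated against known
ground truth; it is deliberately an image-domain model, not a physics
simulation.

**Phantoms.** Four variants: circular bodies of 180/230/280 mm (ED1–ED3,
the larger two being the core phantom wrapped in uniform soft-tissue
bolus) and a 320 × 270 mm ellipse (ED4) whose annulus carries 8 extra
rods; the core carries 9 rods (adipose, breast, muscle, liver, cortical
bone, and hydroxyapatite at 200/800/1000/1250 mg/cc). Rods are 15-mm
radius, one at center and eight on a 57-mm ring (ED4's extras on a
115 × 105 mm elliptical ring), comfortably inside the bodies and apart
from each other. Nominal insert HU at CSCT energy are editable defaults
in `data/ed_phantoms.json` (adipose −70, breast −35, muscle 44, liver 54,
cortical bone 1500, HA rods 220/855/1050/1280, lung −810/−500, body epoxy
30) — plausible tissue-equivalent values chosen for coverage of the HU
axis, not measured reference data. Rasterization assigns each in-plane
voxel center its region's HU; at protocol LDCT the body and insert values
pass through the inverse of the transfer function first (air stays at
−1000 HU on both protocols, as a scanner's HU scale is anchored at air),
then i.i.d. Gaussian noise with the protocol SD (defaults 30 HU CSCT,
15 HU LDCT, the two protocols' tube-current-modulation noise targets) is
added. Default grids mimic 512-matrix reconstructions at protocol FOV
320 mm (CSCT) / 500 mm (LDCT), 5 slices of 3 mm. ROI measurement averages
the middle 3 slices; an ROI larger than its insert shrinks to the insert
radius with a logged warning.

**Patients.** A 128 × 128 × 30 grid at (0.86, 0.86, 3.0) mm — a ~110-mm
cardiac field of view — holds a soft-tissue body (40 HU) with four
disjoint 5-mm-radius tubes tracing gently drifting centerlines (RCA, LAD,
LCX full-length; LM a short segment). Lesion counts per artery are
Poisson with mean 1.5; each lesion is a sphere with peak HU uniform on
[160, 800] and radius uniform on [1.0, 2.5] mm, with a linear falloff to
background over one in-plane voxel — the falloff creates the
partial-volume edge voxels near 130 HU where calibration matters most.
Lesion centers snap to voxel centers (so even the smallest lesion has a
supra-threshold voxel and the recorded lesion count equals the count of
connected truth components) and are kept mutually separated; a lesion
that cannot be placed in a saturated short segment after bounded retries
is dropped and not recorded. The three emitted volumes share one
anatomy: `truth` (noiseless, CSCT energy), `csct` (truth + CSCT noise),
and `ldct` (voxel-wise transfer inverse of truth + LDCT noise).
Ungated acquisition is emulated by a per-slice rigid in-plane translation
of lesion-bearing LDCT slices, N(0, `motion_sigma_mm`) per axis — the
simplest mechanism that degrades score agreement the way high heart rate
does; `motion_sigma_mm` also drives a heart-rate surrogate
(55 + 12·σ bpm) used for subgroup labels. Per-patient seeds derive from
`SeedSequence([master_seed, index])` with separate child streams for
geometry, each protocol's noise, and motion, so cohorts are reproducible
independent of generation order.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: no projection/reconstruction physics (no
beam-hardening streaks, no correlated reconstruction-kernel noise, no
iterative/deep-learning reconstruction texture), no tube-current
modulation, no cardiac-motion kinematics (translation only), no partial
volume beyond the rasterization grid, no patient-to-patient anatomical
variation beyond lesion placement. Results on synthetic cohorts
demonstrate internal consistency of the method, not clinical performance.

## Default study conditions

The shipped end-to-end configuration uses 40 patients, the cubic
reference transfer, protocol noise 30/15 HU, no motion, and phantom-based
curve fitting at matrix 512. On this cohort the uncalibrated total
Agatston bias is strongly negative and calibration removes most of it;
the residual few-unit negative bias is explained by the noise asymmetry —
SD 30 on CSCT inflates lesion peak HU (extreme-value effect over lesion
voxels) and near-threshold area more than the ~15·(d I_CSCT/d I_LDCT)
effective noise of cLDCT does. Test problem sizes (phantom matrices of
128–256 in unit tests, 10-slice scoring volumes) were chosen as the
smallest grids on which the geometric features — ROI discs inside rods,
multi-pixel lesions — are faithfully resolved.

## Numerical choices and edge cases

* HU are floats end to end; volumes are written as float32 NIfTI.
* Axis convention (slice, row, col); in-plane physical coordinates are mm
  from the volume's in-plane center. The NIfTI affine stores
  (thickness, row_mm, col_mm) zooms, so geometry round-trips exactly.
* A non-monotone fitted curve warns rather than errors at construction
  (it may still be applied forward, but its inverse is refused by the
  bracketing check).
* `two_sample_ttest` raises when both samples have zero variance; Welch
  handles a single degenerate side.
* Bland-Altman with n = 2 is allowed (regression fields become NaN below
  n = 3 or with a constant predictor).
* DICOM series reading (slope/intercept applied, slices ordered by
  z-position) is an input convenience; NIfTI is the canonical format and
  nothing is written as DICOM.

## Known limitations

* The calibration is protocol-pair specific by construction; a curve fit
  for one filter/kernel/reconstruction combination does not transfer.
* The ED4 annulus HU values and all insert HU defaults are synthetic
  configuration, so absolute phantom HU have no clinical meaning.
* The motion model cannot reproduce the characteristic arc-shaped
  coronary motion artifacts; it only injects score variance.
* Mass score, risk percentiles and automatic vessel segmentation are out
  of scope.
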