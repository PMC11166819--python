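# Methods

## Signal model and assumptions

A registered free-breathing dynamic series is modeled per lung voxel as

    S_v(t) = S̄_v · (1 + a_v sin(2π f_resp t + φ) + b_v sin(2π f_card t + ψ)) + ε(t)

with a voxel-specific baseline `S̄_v`, a ventilation-driven modulation at
the respiratory rate `f_resp`, a perfusion-driven modulation at the
cardiac rate `f_card`, and broadband noise.  The analysis assumes (i) the
two physiological rates are stable over the ~45 s acquisition, (ii) the
frame rate exceeds twice the cardiac rate, and (iii) registration leaves
approximate voxel correspondence across frames.  Phases are irrelevant to
every downstream quantity; only amplitudes are used.

## Matrix-pencil decomposition

`matrix_pencil_decompose` builds the Hankel matrix of the series with
pencil parameter `L = ⌊N/3⌋` (configurable within `[N/3, N/2]`), truncates
its SVD to the model order, and solves the shifted-invariance least-squares
problem on the dominant right singular vectors; poles are the eigenvalues
of the resulting matrix and complex amplitudes come from a Vandermonde
least-squares fit.  Conjugate pole pairs are merged into real components
(amplitude `2|c|`, or `|c|` for real poles at DC/Nyquist), sorted by
frequency.

Numerical choices:

* **Model order.** `auto` keeps singular values ≥ 1e-2 × the largest —
  adequate for clean region-mean series.  Per-voxel map fits instead use a
  **fixed order of 10** (DC remnant + respiratory + cardiac pairs + slack
  for noise poles): under noise the singular spectrum has no clean gap and
  a relative threshold would be unstable.
* Per-voxel series are demeaned before decomposition so the baseline does
  not dominate the singular spectrum; the mean is retained as the FV
  normalizer.
* Damped poles are retained (the pencil model is inherently damped);
  amplitudes are reported at t = 0.  Pole magnitudes are clamped to
  [0.5, 1.1] in the batched voxel path purely to prevent overflow of
  `z^N` for junk noise poles; physical poles of a ~45 s series are
  unaffected.
* Amplitude read-out at a target frequency accepts the nearest component
  within ±0.1 Hz (configurable); an exact tie breaks toward the lower
  frequency; no match yields amplitude 0.
* Region means accumulate in float64 regardless of storage dtype, so
  baseline selection and frequency estimation are invariant under global
  intensity scaling.

`dft_amplitude_oracle` is a deliberately independent cross-check: on
bin-aligned tones it reads `2|Y_k|/N` straight off the DFT, and the test
suite requires pencil/oracle agreement to 1e-6 on tone sums.

## Cardinal frequency estimation

`f_resp` is the largest-amplitude component of the whole-lung mean series
inside the respiratory band, default **[0.1, 0.6) Hz**; `f_card` the
largest inside the cardiac band, default **[0.6, 3.0] Hz** (capped at
Nyquist), estimated on the heart-region mean when a heart label exists.
The defaults cover pediatric tidal breathing and heart rates and are
configurable since nothing in the method fixes them.  A band with no
component above 3× a noise floor (median single-bin DFT amplitude of the
demeaned series — the Rayleigh-median noise level, insensitive to isolated
tones) raises an error naming the band.

## Maps and the defect rule

`FV_v = A_resp,v / S̄_v` ("fractional" read as amplitude relative to
baseline signal; the config exposes the normalizer for future variants);
`Q_v = A_card,v` is left in raw signal units because the defect rule is
scale-invariant per slice.  A lung voxel is defective iff its value is
**strictly** below `0.70 ×` the median over the lung voxels of its own
slice — the strict inequality makes an all-equal slice defect-free, the
only behavior consistent with healthy lungs not being 100 % defective.
The median includes the candidate voxel itself, and slices without lung
voxels contribute nothing.

## Defect metrics

* VDP/QDP: `100·|defect|/|lung|`.  Per side the **whole-lung denominator**
  is used, so side values add exactly to the whole-lung percentage — the
  convention under which the published per-side group means (8.62 + 6.91)
  reproduce the whole-lung value (15.53).
* VQD_match: `100·|V ∩ Q|/|lung|`; per side with the side's own voxels as
  reference (published side VQD values average, not sum, to the whole-lung
  value, which is what this convention produces).
* DDI: computed in-plane per slice (2D multi-slice acquisition with 12 mm
  slices makes through-plane adjacency physically different).  Each defect
  voxel scores `ρ_i √c_i`, where `ρ_i` is the occupied fraction of the
  punctured Euclidean disc of radius **R = 3 voxels** and `c_i` its
  8-connected component size; slices combine weighted by defect count.
  This is a concrete instantiation of a "dense and aggregated" clustering
  index; values are arbitrary units, comparable only within a fixed
  configuration (R and the radius are exposed in the config), zero iff
  there are no defects, and invariant to translation and slice order.

## Preprocessing

Baseline = the frame whose whole-lung mean is closest to the temporal
median of the whole-lung mean (mid-respiratory state), ties to the
earliest frame.  Registration is **integer in-plane translation per slice
per frame**, maximizing FFT cross-correlation with the baseline frame
(the spectral stage needs only approximate correspondence; deformable
registration is out of scope).  Estimates with a normalized correlation
peak below 0.3 (e.g. pure-noise frames) fall back to zero shift with a
logged warning; shifts above a quarter of the grid raise an error.
Out-of-frame voxels are edge-filled.  The Otsu-based fallback segmentation
(two largest dark non-border components, sides by centroid column) is for
phantom data only; real masks are inputs, and anatomical side labels are
always taken from the mask, never inferred from image orientation.

## Phantom generator

The phantom emulates: two elliptical lungs per slice tapering across
slices, a cardiac notch and a heart region with cardiac-only modulation,
smooth spatially heterogeneous amplitude fields (Gaussian-smoothed white
noise, kernel 4 voxels in-plane, rescaled to mean 0.12/0.03 and CV 0.25),
a contiguous planted defect blob grown from a random seed voxel on one
side (attenuation 0.4 by default), Gaussian noise (sd 2 % of lung
baseline), and optional integer bulk translation locked to the breathing
phase.  Geometry defaults mirror the acquisition: 10 slices, 96×96 grid,
150 frames at 3.3 Hz, 3.3×3.3×12 mm voxels, f_resp = 0.30 Hz,
f_card = 1.25 Hz.  The amplitude heterogeneity is what makes healthy
phantoms show a nonzero background defect rate under the relative-median
rule, as healthy controls do.

It does **not** emulate: realistic anatomy, MR physics (coil profiles,
k-space, banding), deformable breathing motion, amplitude distributions
calibrated to any real cohort (none are published for this method), or
through-plane motion.  Passing recovery tests therefore demonstrates
correctness of the numerical chain under the stated signal model, not
clinical performance.

The cohort simulator draws per-subject outcomes from group-specific
normals and per-side pairs from correlated bivariate normals (default
within-subject side correlation 0.5, chosen so that the implied whole-lung
SDs are of the same order as the published ones); its default means/SDs/n
are the published group summaries shipped in `cohort_stats`.

## Cohort statistics

Post-hoc contrasts are computed **from group summaries** (mean, SD, n) so
published tables can be reproduced without subject-level data:
Tukey-Kramer uses the pooled within-group MSE and the studentized-range
quantile with df = N − k; Games-Howell uses per-pair variances with Welch
df.  Outcome → method mapping (Tukey for FEV₁, FVC, TLC, RV/TLC, LCI,
QDP, VQD_match; Games-Howell for FEV₁/FVC and VDP; BH for the DDIs)
matches the reference analysis and is overridable.  For BH-route outcomes
the mean difference and an unadjusted Welch CI are reported with the
BH-adjusted p across the pairwise family; the published BH-adjusted CIs
are asymmetric and their construction is unstated, so they are not
reproduced.  The mixed group × side ANOVA is delegated to pingouin, with
degenerate effects (sum of squares at numerical zero, e.g. identical
sides) mapped to F = 0, p = 1.  Paired side contrasts use a per-group
paired t with Bonferroni adjustment over the groups tested.  Raw-mode
one-way ANOVA goes through `scipy.stats.f_oneway`; summary mode uses the
algebraically identical pooled-SS form, and the suite checks both routes
agree to 1e-10.  α = 0.05 throughout; missing outcomes are handled
per-outcome complete-case.

## Problem sizes and tolerances used in the test suite

* Unit tests run on reduced phantoms (4 slices, 48×48, 120 frames); the
  planted-defect recovery test runs 10 phantoms at the full acquisition
  geometry (10 × 96 × 96 × 150), tolerance ±3 percentage points against
  direct thresholding of the true amplitude field.
* The noiseless per-voxel FV check uses a 1e-3 absolute tolerance: the
  pencil amplitude is exact, but the temporal-mean normalizer retains a
  finite-sample sinusoid mean bounded by `a/(N sin(π f_resp/fs))`
  (≈ 3e-4 for the default phantom), which dominates the error.
* `scripts/acceptance.py` analyzes 3 full-geometry phantoms and runs
  1000 null replicates of the statistics chain; both complete in about a
  minute.
* Null calibration: the mixed-ANOVA interaction p is checked for
  uniformity (KS at 0.01, 500 replicates of exchangeable-side cohorts),
  and the ANOVA-gate + post-hoc chain for a family type-I error ≤ 0.06 at
  nominal 0.05.

## Known limitations

* Translation-only, per-slice registration; strong deformable motion will
  blur amplitudes rather than fail loudly.
* Global `f_resp`/`f_card` with ±0.1 Hz matching per voxel; voxel-wise
  free frequency fitting is not attempted.
* DDI magnitudes depend on R and the in-plane convention and are not
  comparable across configurations or to other clustering indices.
* Absolute ventilation/perfusion (air/blood flow in physical units) is
  out of reach of the method; all quantities are relative.
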