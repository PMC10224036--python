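# Methods

## Forward model

The simulator describes each voxel's Z-spectrum as direct water
saturation plus exchange-mediated pools, using the standard
sum-of-Lorentzians phenomenology:

    Z(Δω) = 1 − Σ_i A_i · b1 · (w_i/2)² / ((w_i/2)² + (Δω − δ_i − b0)²)

with peak depth `A_i`, FWHM `w_i` (ppm), centre `δ_i` (ppm), the local
static-field offset `b0` (ppm) displacing every resonance, and the local
relative RF field `b1` scaling every amplitude (first-order saturation
efficiency). Z is clipped to [0, 1]; an amplitude sum that would drive
Z below zero before clipping is rejected as unphysical rather than
silently truncated.

Default pool set (per-voxel, inside/outside the ROI):

| pool      | δ (ppm) | A (depth) | w (ppm) | role |
|-----------|---------|-----------|---------|------|
| water     | 0.0     | 0.80      | 1.4     | direct saturation |
| glu_amine | +3.0    | 0.03–0.06 | 1.0     | glutamate contrast (group-dependent) |
| noe       | −3.5    | 0.02      | 3.0     | upfield NOE background |

The water depth of 0.80 keeps `A·b1 < 1` for relative B1 up to 1.25
under the linear scaling, so the model stays physical across the field
ranges the phantoms use. The NOE pool makes the simulated MTR asymmetry
turn negative above ≈4 ppm, the pattern seen in vivo at high field. The
mapping from glutamate concentration to `A` is treated as a single free
linear coefficient; group ground truths are config parameters
(`GroupSpec.glu_amplitude`), not hard-coded to any published means, so
recovery tests are not circular.

A two-pool **Bloch–McConnell** integrator (6-state coupled
magnetisation ODE under continuous-wave saturation, solved exactly by
matrix exponential of the augmented 7×7 system) provides an independent
physics oracle. The test suite matches its extracted CEST line to the
Lorentzian model in the slow-exchange regime (solute fraction 0.001,
exchange rate 100 s⁻¹ at 300 MHz, 1 µT) and requires the two MTR
asymmetries at 3 ppm to agree in sign and within a declared 5% relative
tolerance (measured agreement is ≈0.6%). The exchange regime behind
in-vivo GluCEST contrast is not asserted; these oracle parameters are
literature-typical slow-exchange values chosen for a clean comparison.

Acquisition defaults mirror a 7 T rodent protocol: 25 CEST offsets
−6…+6 ppm (0.5 ppm steps), saturation 3.6 µT × 1 s; 33 WASSR offsets
−0.8…+0.8 ppm (0.05 ppm steps) at 0.3 µT; dual flip angles 30°/60°;
96×96 matrix (tests and the bundled study driver use 16×16 or 12×12 for
desk-scale runtimes — results are geometry-independent because all
processing is voxelwise).

Noise is **Rician** (magnitude of the complex signal plus i.i.d.
Gaussian quadrature noise), with sigma expressed as a fraction of the S0
level; a Gaussian flag exists. The default study noise level is 1% of
S0, a typical high-SNR preclinical value. All randomness derives from
one study seed through `SeedSequence(entropy, spawn_key=(group,
subject))`, so adding subjects never reshuffles existing ones and
regeneration is bit-identical.

## B0 correction

WASSR centre frequencies are estimated per voxel from the spectrum
minimum: a cubic-spline interpolant minimised on a 0.001 ppm sub-grid
(default), or a symmetric-Lorentzian least-squares fit (classic WASSR
practice). A minimum at either grid end, or a flat spectrum, marks the
voxel invalid — never extrapolated. On noiseless phantoms with smooth
fields up to ±0.3 ppm the recovery RMSE is below 0.01 ppm.

Re-referencing resamples each CEST spectrum at `offsets + shift`. The
default interpolant is **barycentric rational (AAA)**: a sum of
Lorentzians is a rational function of the offset, so rational
interpolation reproduces it to machine precision, whereas a cubic spline
on the 0.5 ppm grid loses up to ~0.6 GluCEST percentage points at the
narrow 3 ppm shoulder for shifts ≤ 0.3 ppm — more than the corrections
themselves are worth. Noise breaks rationality and shows up as spurious
poles; any fit with a pole closer than 0.25 ppm to the real axis inside
the sampled range (true Lorentzian poles sit at least half a linewidth
away) is rejected and that voxel falls back to the cubic spline, whose
interpolation bias is then small against the noise itself. `cubic` and
`linear` modes can be forced. Offsets whose shifted target leaves the
acquired range are flagged per-offset invalid.

## B1 handling

The double-angle inversion `arccos(S_2α/(2·S_α))/α_nominal` is exact on
noiseless inputs; out-of-domain ratios (noise, signal voids) invalidate
the voxel. Because protocols state that relative B1 maps "were
calculated" far more often than how they were applied, the application
is an explicit, logged policy: `scale` (divide the GluCEST value by the
relative B1; first-order, order-independent with B0 correction since it
acts on the final map), `exclude` (drop voxels with |rel−1| > 0.3 by
default), or `none`. The default is `scale`.

## Quantification conventions

The GluCEST denominator is S_sat(−3.0 ppm) — the symmetric upfield
reference — not S0, matching the printed formula convention even though
CEST literature varies. ±3.0 ppm are taken as on-grid samples after B0
resampling (the default grid contains them by construction). ROI
statistics use the sample (n−1) SD. Published "mean ± value" group
tables are interpreted as mean ± SD.

## Statistics

Raw-data and summary-statistic ANOVA are the same computation
(`SS_between = Σ nᵢ(x̄ᵢ − x̄)²`, `SS_within = Σ (nᵢ−1)sdᵢ²`), verified as
an exact identity by property test. Tukey HSD uses
`q = |x̄ᵢ − x̄ⱼ| / √(MS_w/n)` (Tukey–Kramer SE for unequal n) with the
studentized-range distribution; it cross-checks against statsmodels'
implementation. Power uses the noncentral F distribution with
`λ = f²·k·n` — the G*Power total-N convention for Cohen's f, stated
explicitly because `λ = f²·n` and `λ = f²·(N−k)` conventions also
circulate; only the total-N convention reproduces an achieved power of
0.86285 for k=3, n=7, f=0.8, α=0.05. Sample-size search is the smallest
integer n reaching the target power (bounded at 10⁴).

One caveat worth recording: re-analysing a published three-group table
of (2.03±0.45, 2.60±0.43, 3.62±0.38; n=7) gives a Tukey-adjusted
p ≈ 0.052 for the smallest contrast — two-decimal rounding of means and
SDs is enough to move a borderline contrast across the 0.05 line, so
summary-based re-analysis should not be over-read near thresholds. The
extreme contrast (q ≈ 9.99, p ≈ 4×10⁻⁶) is rounding-robust.

The Monte-Carlo calibration tests (2,000 replicates of the k=3, n=7
design) check that the empirical type-I error is 0.05 ± 0.015 and that
empirical power at f = 0.8 is within ±0.03 of the analytic 0.86285.

## What the phantom does and does not emulate

It emulates: offset grids and saturation parameters of a single-slice
protocol, smooth B0/B1 fields, an elliptical hippocampus-like ROI with
higher glutamate amplitude than the background, Rician magnitude noise,
and group contrast through pool amplitude. It does **not** emulate:
readout-sequence effects (TR/TE, turbo-RARE weighting), semi-solid MT
super-Lorentzian backgrounds, pH/temperature dependence of exchange,
multi-slice geometry, motion, or partial-volume anatomy. Passing
recovery tests therefore demonstrates correctness of the processing
chain under the stated forward model, not robustness to every in-vivo
confound.

## Numerical choices

- WASSR fine-grid refinement step: 0.001 ppm.
- Rational-resampling pole guard: 0.25 ppm (half the narrowest default
  linewidth).
- B1 double-angle domain: ratios outside [−1, 1] invalidated; nominal
  angle restricted to (0°, 90°).
- Degenerate inputs raise: flat WASSR spectra, empty masks, zero S0
  voxels (dropped and logged), all-identical ANOVA groups (F undefined),
  zero within-group variance with unequal means (F = ∞, flagged).
- `lorentzian_z` clip tolerance 1e−9 for the unphysical-amplitude guard.
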