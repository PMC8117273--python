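# Methods

This note documents the models, defaults and design choices behind
`cardiomrs`, and what the synthetic-data tests do and do not demonstrate
about scanner data.

## Signal model and conventions

A shot is a complex FID sampled every `dwell_s` seconds (default 0.4 ms,
2.5 kHz bandwidth, 2048 points — the acquisition grid is configurable; the
defaults are assumptions, not protocol constants). The ppm axis maps DFT
frequency f to `reference_ppm + f / f0_mhz` with the carrier on water
(4.7 ppm) and is reported in descending ppm, so water appears left of the
lipid methylene peak at 1.3 ppm. Lorentzian singlets decay as
`exp(−π·LW·t)` and Gaussian singlets as `exp(−(π·LW·t)²/(4 ln 2))`; both
conventions give a spectral FWHM equal to LW.

Creatine N-methyl (3.027 ppm) and trimethyl-amide (3.183 ppm) are modeled
as singlets; J-coupling evolution is out of scope, which is consistent
with fitting only the resonances listed above. Triglycerides are six
Gaussian components (0.9/1.3/1.6 ppm fatty-acid and 2.1/2.3/2.8 ppm
unsaturated fatty-acid groups).

## Preprocessing

* **Autophasing.** Every spectral peak above 20% of the maximum
  contributes one phase sample: the angle of the spectrum summed over a
  window symmetric (with fractional-bin edges) about the peak's sub-bin
  centroid, evaluated on an internally zero-filled grid. Symmetry cancels
  the odd dispersive part, so the sample is insensitive to off-grid peak
  positions; fitting raw unwrapped point-wise phases instead would be
  dominated by the intrinsic dispersion slope of each line. The
  first-order term is the weighted least-squares slope across peaks (zero
  when only one peak exists); the zeroth-order term then makes the tallest
  peak real-positive. Whether the original analysis phased on the water
  peak or the full spectrum is unknown; the tallest-peak rule is an
  assumption.
* **SVD coil combination.** Channel weights are the dominant eigenvector
  of the channel covariance of the per-channel-phased data; shots are
  conjugate-weight summed with unit-norm weights (noise SD is preserved)
  and a final global phase makes the tallest peak of the mean spectrum
  real-positive. Dead (all-zero) channels are passed through unphased and
  receive ~zero weight.
* **Order of operations.** Phasing → combination → realignment →
  gating/averaging → zero-filling → apodization. Realignment must precede
  averaging to be meaningful, even though processing lists conventionally
  name zero-filling earlier.
* **Apodization** is exponential (`exp(−π·lb·t)`, default 10 Hz), adding
  `lb` to Lorentzian linewidths; a Gaussian alternative is available.
* **Metrics.** FWHM is measured on the real part of the phased spectrum
  (magnitude-mode Lorentzian widths would be √3 wider); SNR is the
  real-part peak height within ±0.15 ppm of the nominal position divided
  by the SD of the real part in −3…−1 ppm. Exclusion uses strict
  inequalities (water LW > 35 Hz, SNR < 5 fail; the boundary passes).

## Retrospective gating

Shots are characterized on the residual water peak (4.7 ± 0.5 ppm,
magnitude-spectrum search on a 4× zero-filled grid). The frequency
estimate is the centroid of |S|² over the contiguous half-maximum region;
the phase is the angle of the complex sum over that region (the dispersive
part cancels by symmetry). A 3-point parabola on the zero-filled grid is
*not* used for the frequency: for a ~14 Hz-wide line on a 0.3 Hz grid its
curvature is noise-dominated, and phase errors track frequency errors
almost perfectly through the line's phase slope.

* **Stage 1 (adaptive linewidth threshold).** The published description
  leaves the search underspecified; the implementation is a deterministic
  greedy walk: start at the threshold admitting the best quartile by water
  linewidth, step by 1 Hz, re-average the admitted shots and accept the
  step while the FA (1.3 ppm) SNR is maintained or increased — "maintained"
  within a 2% tolerance of the running best, with smaller resulting FA
  linewidth breaking exact ties. The SNR of an n-shot average is computed
  as peak height · √n over a pooled single-shot noise floor (median across
  shots), so the quantity varies smoothly with the admitted set instead of
  inheriting the variance of re-estimated noise windows. The full
  (threshold, SNR, LW) trace is returned so alternative stop rules can be
  compared.
* **Stage 1 averages are frequency-corrected but *not* phase-corrected.**
  The SNR cost of phase-corrupted shots is exactly the effect the
  two-stage gate exists to remove; correcting phases inside the evaluation
  would hide it.
* **Stage 2 (phase gate).** Reject shots whose water phase deviates more
  than k·SD (k = 0.6) from the circular mean; the SD is taken over the
  whole scan (all shots), configurable to survivors only. Under Gaussian
  phase corruption this rejects 2(1−Φ(k)) ≈ 55% of shots at k = 0.6 —
  matching the ~50% free-breathing rejection fractions such protocols
  report.
* **Final averaging** applies both the frequency and phase estimates of
  each accepted shot. Bookkeeping is exact:
  `n_used + n_rejected_lw + n_rejected_phase = n_shots`.

## Model fitting

Nonlinear least squares (trust-region reflective, analytic Jacobian) on
the stacked real/imaginary residual of the time-domain model. Free
parameters: non-negative amplitudes, one shift per group (Cr, TMA, FA,
UFA, water; bounded ±0.1 ppm), shared Lorentzian damping d ∈ [0, 50] Hz,
global phase. Per-component shifts are available but increase collinearity
between the 2.1/2.3 ppm neighbors. Initialization: phase from autophasing,
amplitudes from real-part peak integrals (overlap ignored), δ = 0,
d = 5 Hz. Defaults for the basis widths — 25 Hz Gaussian for TG, 6 Hz
Lorentzian for Cr/TMA, 10 Hz for water — are assumptions, configurable.
Non-negativity is imposed to stabilize low-SNR fits. The initial and final
cost are recorded; the final never exceeds the initial.

When residual water is present (it always is in water-suppressed scans —
gating depends on it), the pipeline keeps the water component in the
basis; leaving ~1% residual water unmodeled biases the metabolite
amplitudes upward by tens of percent because the fit is time-domain over
the full FID.

CRLBs: `F = (1/σ²)·Re(JᴴJ)` over all free parameters at the optimum,
`CRLB_m = sqrt((F⁻¹)_mm)`, with σ the per-component (real/imag) noise SD
from the final 10% of the raw, unfiltered FID. A tail that still shows
decay structure (first half > 3× the power of the second) triggers a
warning, since the SD would then be overestimated. Singular or
conditioning-degenerate Fisher matrices are reported as unbounded with an
ill-conditioning flag, as are relative CRLBs beyond a configurable ratio
(duplicate/collinear components).

## Quantification

The correction `S* = S·[1/(1−exp(−TR/T1))]·exp(TE/T2)` uses the effective
repetition period (2·RR when ECG triggering forces it). STEAM signals are
additionally corrected by `exp(TM/T1)`; STEAM's intrinsic factor-two
signal loss is *not* corrected (an optional flag exists), mirroring
standard practice of correcting only relaxation. In-vivo defaults:
T1 = 0.35 s (lipids), 1.20 s (water), 1.00 s (Cr); T2 = 89 ms (lipids),
135 ms (Cr), 44 ms (water). Phantom mode disables the T1 term (TR ≫ T1)
and uses T2 = 57.37 ms (FA at 1.3 ppm) and 249.5 ms (water).

Naming of the proton-count equations: the 2/28 equation quantifies the
single 1.3 ppm methylene peak and is reported as [FA]; the 2/93 equation
quantifies the summed six-component TG signal and is reported as [TG].
UFA components use the lipid relaxation constants. The water reference
[W] = 55.5 mol/L · 0.727 · 1000 is implemented verbatim; its units
(µmol/g from a molarity times a weight fraction) are dimensionally loose,
which is noted rather than repaired, and the constant is overridable for
phantoms.

The CSDE Δf uses water (4.7 ppm) vs methylene (1.3 ppm), i.e. 3.4 ppm at
123.2 MHz ≈ 419 Hz — this pairing, not 3.5 ppm, reproduces the 36/25/19%
values for the 1150/1700/2200 Hz bandwidths.

## Synthetic data

The generator emulates three scenarios with full ground-truth records:

* **Breath-hold**: 8 water-suppressed averages, small residual instability
  (phase SD 0.05 rad, frequency SD 0.5 Hz, linewidth jitter 0.5 Hz).
* **Free-breathing**: 100 averages with per-shot Gaussian draws — phase
  SD 0.3 rad, frequency SD 3 Hz, linewidth jitter SD 4 Hz. Gaussian is the
  minimal model consistent with characterizing shots by exactly these
  quantities, and makes the 0.6·SD phase gate analytically checkable.
  Linewidth jitter is applied as |draw| (half-normal): breathing broadens
  lines, and a negative additive linewidth would make the FID grow
  exponentially. An optional labeled fraction of shots carries +30 Hz
  linewidth and 5× phase noise to emulate gross-motion corruption.
* **Phantom**: water + FA(1.3 ppm) with the true amplitude ratio set by
  the voxel/tube geometry, optionally scaled by a caller-supplied overlap
  factor; no breathing.

Default amplitudes give Cr/W ≈ 0.032%, FA/W ≈ 0.22%, TG/W ≈ 0.68% before
relaxation correction (healthy-myocardium orders of magnitude; defaults,
not truths). Residual water is 5% of the unsuppressed water amplitude.
The default noise SD (1.5·10⁻³ per real component per channel) was chosen
so the gated free-breathing average shows FA SNR near 100 and Cr SNR of a
few tens — the order reported for free-breathing cardiac protocols; the
per-shot residual-water SNR is then comfortably above the ~20 needed for
reliable shot characterization. Four fixed complex coil sensitivities
emulate the receive array.

Ground truth records every per-shot draw and the concentrations implied by
the quantification equations at the true amplitudes (the simulator does
not model relaxation decay, so truth and estimate traverse the same
correction; relaxation correctness is tested separately through its
closed-form identities).

**What passing tests do not show:** the generator has no baseline, no
macromolecules, no eddy-current or lineshape distortion, no intra-shot
motion, no J-coupling multiplets, and breathing draws are i.i.d. rather
than quasi-periodic. Recovery numbers on synthetic subjects therefore
bound estimator behavior under the stated model, not scanner performance.

## Numerical choices and problem sizes

Fits run on 1024–2048-point grids with analytic Jacobians; tolerances
1e−12 (xtol/ftol/gtol), at most 400 function evaluations. Monte-Carlo
checks use 100 seeds (amplitude bias at spectral SNR ≈ 40), 500 seeds
(CRLB vs MC SD), 200 draws (√2 coil-combination gain), and three seeded
subjects for the end-to-end recovery — sizes chosen to keep the whole
suite under a minute while leaving Monte-Carlo error well inside the
asserted tolerances. Degenerate inputs (all-zero FIDs, zero phase
variance, empty post-gating shot sets, non-decaying T2 series, constant
regressors, zero ICC variance) raise explicit errors or flags rather than
propagating NaNs.

## Known limitations

* No vendor raw-file parsers (TWIX/rda/DICOM-MRS); data enter through the
  documented HDF5 container.
* No baseline model, macromolecule components or HLSVD water removal; the
  water line is handled inside the basis instead.
* The adaptive-threshold stop rule is one deterministic reading of an
  underspecified procedure; the recorded trace makes alternatives easy to
  evaluate.
* ICC is ICC(A,1) (two-way, absolute agreement, single measurement);
  other forms can be derived from the same mean squares but are not
  exposed.
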