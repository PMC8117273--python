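# cardiomrs

Processing and quantification for **cardiac single-voxel ¹H magnetic
resonance spectroscopy (MRS) at 3 T**: from raw multi-channel, multi-average
complex free-induction decays (FIDs) to relaxation-corrected,
water-referenced concentrations of myocardial creatine (Cr) and
triglycerides (TG), with retrospective respiratory gating for free-breathing
acquisitions.

It is written for MR physicists and spectroscopists who acquire
single-voxel spectra in the interventricular septum with PRESS, sLASER or
STEAM and need a tested, scriptable alternative to one-off analysis code —
including a synthetic-data generator with known ground truth, so every
stage of the pipeline can be validated without scanner data.

## What it computes

**Signal chain.** Per-channel automatic 0th/1st-order phasing → SVD coil
combination (weights = dominant singular vector of the channel × data
matrix) → per-shot frequency realignment → averaging or retrospective
gating → zero-filling and 10 Hz exponential apodization, plus spectral
quality metrics (water FWHM at 4.7 ppm; peak SNR against the noise floor in
−3…−1 ppm; exclusion rules LW > 35 Hz, SNR < 5).

**Retrospective gating** (free-breathing series). Each shot is
characterized by the amplitude, linewidth, frequency and phase of its
residual water peak. Stage 1 rejects broad shots using an adaptive
linewidth threshold: starting from the best quartile, the threshold grows
in 1 Hz steps while the fatty-acid (1.3 ppm) SNR of the running average is
maintained or increased. Stage 2 rejects shots whose water phase deviates
more than k·SD (k = 0.6) from the circular mean. Accepted shots are
frequency- and phase-corrected, then averaged; every rejection is logged.

**Model fitting.** Time-domain linear-combination fit

    y(t) = e^{iφ} e^{−π d t} Σ_m a_m e^{i2πδ_g(m) t} b_m(t)

with non-negative amplitudes *a_m*, one frequency shift per metabolite
group, a shared Lorentzian damping *d* and a global phase φ. The basis
holds Lorentzian singlets for Cr (3.027 ppm) and trimethyl-amide
(3.183 ppm) and six Gaussian TG components — fatty acids (FA) at 0.9, 1.3,
1.6 ppm and unsaturated FA at 2.1, 2.3, 2.8 ppm. Cramér–Rao lower bounds
per amplitude come from the Fisher information F = (1/σ²)·Re(JᴴJ) with the
noise SD σ measured on the raw FID tail.

**Quantification.** Relaxation correction
S\*<sub>N</sub> = S<sub>N</sub> · [1/(1−e^{−TR/T1})] · e^{TE/T2} (plus
S\*\* = S\*·e^{TM/T1} for STEAM), then water-referenced concentrations

    [Cr] = 2/3  · [W] · S*_Cr / S*_W
    [FA] = 2/28 · [W] · S*_FA(1.3) / S*_W
    [TG] = 2/93 · [W] · S*_TGsum / S*_W,   [W] = 55.5 · 0.727 · 1000 µmol/g

with literature myocardial T1/T2 defaults and a phantom table (T2-only) for
in vitro work. Localization analytics are included: the chemical-shift
displacement error CSDE = Δf/BW and the phantom geometry prediction
FA/W = 100·(π r_in²)/(A_box − π r_out²).

**Repeatability statistics.** Bland–Altman bias and 1.96·SD limits of
agreement, test–retest ICC(A,1) from two-way ANOVA mean squares, and OLS
regression with Pearson r for paired breath-hold / free-breathing scans.

## Worked example

Simulate a 100-shot free-breathing acquisition (4 channels, breathing
corruption) together with its non-suppressed water companion scan, then run
the full pipeline:

```bash
cardiomrs simulate --scenario fb --seed 7 --with-water-ref --out fb.h5
cat > config.json <<'EOF'
{ "input": "fb.h5", "water_input": "fb.h5.water.h5", "mode": "fb" }
EOF
cardiomrs run --config config.json --output-dir out
```

which prints

```
used 50/100 shots; fit converged=True; qc_pass=True
[Cr] = 4.849 umol/g
[FA] = 3.091 umol/g
[TG] = 2.895 umol/g
```

Half the shots were rejected (here all by the 0.6·SD phase gate — the
simulated breathing phase noise is Gaussian, for which that gate removes
~55% by construction), the water linewidth of the average was 25.4 Hz and
the Cr/FA peak SNRs (79/143) clear the exclusion thresholds; the
concentrations recover the scenario's simulated truth to within the fit's
Cramér–Rao uncertainty. `out/` additionally contains `shotqc.csv` (one row
per shot with the accept/reject decision), `fit.csv` (amplitudes and
CRLBs), `concentrations.csv` and `rejections.log`.

The same stages are available as `cardiomrs
simulate|preprocess|gate|fit|quantify|stats` subcommands and as library
functions (`cardiomrs.svd_combine`, `cardiomrs.gate_and_average`,
`cardiomrs.fit_spectrum`, `cardiomrs.concentrations`, …).

## Data format

FID series are stored in a small self-describing HDF5 container:
`/series/real` and `/series/imag` (float64, shot × channel × time),
`/series/shot_index`, and one scalar attribute per acquisition parameter
(sequence, TE/TR/TM, transmitter frequency, dwell time, array sizes,
refocusing bandwidth, voxel extents, water-suppression flag, reference
ppm). `cardiomrs.io.to_nifti_mrs_header` / `from_nifti_mrs_header`
translate the metadata subset that has a NIfTI-MRS standard key.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
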