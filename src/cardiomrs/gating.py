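"""Two-stage retrospective gating of free-breathing shot series.

Breathing corrupts individual averages with phase, frequency and linewidth
fluctuations of the (residual) water resonance.  Gating proceeds in two
stages on the combined single-channel series:

1. **Adaptive linewidth threshold** — starting from the threshold admitting
   the best quartile of shots by water linewidth, the threshold grows in
   1 Hz steps; a step is kept only while the fatty-acid (1.3 ppm) SNR of
   the average of admitted shots is maintained or increased, with smaller
   resulting FA linewidth breaking SNR ties.  The full (threshold, SNR,
   LW) trace is recorded.
2. **Phase gate** — shots whose water-peak phase deviates from the circular
   mean by more than ``k x SD`` (k = 0.6 by default, SD over the whole
   scan) are rejected.

Accepted shots are phase- and frequency-corrected with their own water-peak
estimates before averaging.  Bookkeeping is exact:
``n_used + n_rejected_lw + n_rejected_phase = n_shots`` always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FIDSeries, Spectrum, ValidationError
from .preprocess import apodize, fwhm, noise_sd_spectrum, to_spectrum, wrap_phase

WATER_PPM = 4.7
WATER_SEARCH_PPM = 0.5
FA_PPM = 1.3


@dataclass
class ShotQC:
    """Per-shot water-peak characterization and accept/reject bookkeeping."""

    shot: int
    water_amp: float
    water_lw_hz: float
    water_shift_hz: float
    water_phase_rad: float
    detected: bool = True
    accepted: bool = True
    reject_reason: str = "none"

    def reject(self, reason: str) -> None:
        self.accepted = False
        self.reject_reason = reason


@dataclass
class GatingResult:
    """Outcome of the two-stage gate on one series."""

    lw_threshold_hz: float
    n_rejected_lw: int
    n_rejected_phase: int
    n_used: int
    averaged_fid: np.ndarray
    shots: list[ShotQC]
    fa_snr_trace: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def n_shots(self) -> int:
        return self.n_used + self.n_rejected_lw + self.n_rejected_phase


# ---------------------------------------------------------------------------
# Shot characterization


def characterize_shots(
    series: FIDSeries, *, zero_fill_factor: int = 4
) -> list[ShotQC]:
    """Estimate water-peak amplitude, linewidth, shift and phase per shot.

    The residual water peak is located on the magnitude spectrum within
    4.7 ± 0.5 ppm (parabolic sub-bin refinement); the phase is the complex
    angle of the peak bin *before* per-shot phasing, the amplitude the
    real-part height after it.  Raises if no water peak is detectable in
    more than half of the shots.
    """
    if series.n_channels != 1:
        raise ValidationError("characterize expects a combined (single-channel) series")
    acq = series.acq
    n_fft = acq.n_points * zero_fill_factor
    freqs = np.fft.fftshift(np.fft.fftfreq(n_fft, d=acq.dwell_s))
    ppm = acq.reference_ppm + freqs / acq.f0_mhz
    win = np.abs(ppm - WATER_PPM) <= WATER_SEARCH_PPM
    idx_win = np.flatnonzero(win)
    noise_win = (ppm >= -3.0) & (ppm <= -1.0)
    df = 1.0 / (n_fft * acq.dwell_s)

    out: list[ShotQC] = []
    n_undetected = 0
    for i in range(series.n_shots):
        spec = np.fft.fftshift(np.fft.fft(series.data[i, 0, :], n=n_fft))
        mag = np.abs(spec)
        k_local = int(np.argmax(mag[idx_win]))
        k = idx_win[k_local]
        noise_sd = float(np.std(spec.real[noise_win], ddof=1))
        detected = noise_sd == 0 or mag[k] > 5.0 * noise_sd

        # sub-bin peak position: centroid of |S|^2 over the contiguous
        # half-maximum region (robust for lines much wider than the grid)
        lo = k
        while lo > 0 and mag[lo - 1] >= 0.5 * mag[k]:
            lo -= 1
        hi = k
        while hi < n_fft - 1 and mag[hi + 1] >= 0.5 * mag[k]:
            hi += 1
        region = slice(lo, hi + 1)
        w2 = mag[region] ** 2
        pos = float(np.sum(np.arange(lo, hi + 1) * w2) / np.sum(w2))
        shift_hz = float(
            (np.interp(pos, np.arange(n_fft), ppm) - WATER_PPM) * acq.f0_mhz
        )
        # phase of the complex sum over the (near-symmetric) peak region:
        # the dispersive part cancels, leaving the shot's water phase
        phase = float(np.angle(np.sum(spec[region])))

        phased = spec * np.exp(-1j * phase)
        amp = float(phased.real[k])
        sp = Spectrum(
            values=phased[::-1], ppm_axis=ppm[::-1], hz_per_ppm=acq.f0_mhz
        )
        try:
            lw = fwhm(sp, WATER_PPM + shift_hz / acq.f0_mhz, WATER_SEARCH_PPM)
        except ValidationError:
            lw = math.nan
            detected = False
        if not detected:
            n_undetected += 1
        out.append(
            ShotQC(
                shot=int(series.shot_index[i]),
                water_amp=amp,
                water_lw_hz=lw,
                water_shift_hz=shift_hz,
                water_phase_rad=float(wrap_phase(phase)),
                detected=detected,
            )
        )
    if n_undetected > series.n_shots / 2:
        raise ValidationError(
            "no detectable water peak in more than half of the shots; "
            "use a non-suppressed reference or check water suppression level"
        )
    return out


def _corrected_average(
    series: FIDSeries,
    shots: list[ShotQC],
    mask: np.ndarray,
    *,
    correct_phase: bool = True,
) -> np.ndarray:
    """Average the selected shots after frequency (and optionally phase)
    correction with their own water-peak estimates.

    The stage-1 threshold search averages without phase correction: the SNR
    cost of phase-corrupted shots is exactly what the search must see (and
    what the phase gate subsequently removes)."""
    t = series.acq.time_axis_s
    acc = np.zeros(series.acq.n_points, dtype=np.complex128)
    n = 0
    for i, keep in enumerate(mask):
        if keep:
            qc = shots[i]
            corr = np.exp(-2j * np.pi * qc.water_shift_hz * t)
            if correct_phase:
                corr = corr * np.exp(-1j * qc.water_phase_rad)
            acc += series.data[i, 0, :] * corr
            n += 1
    if n == 0:
        raise ValidationError("all shots rejected: nothing to average")
    return acc / n


# ---------------------------------------------------------------------------
# Stage 1: adaptive linewidth threshold


def auto_lw_threshold(
    shots: list[ShotQC],
    series: FIDSeries,
    *,
    step_hz: float = 1.0,
    start: str = "quartile",
    apodize_lb_hz: float = 10.0,
    fa_ppm: float = FA_PPM,
    snr_tol: float = 0.02,
) -> tuple[float, list[tuple[float, float, float]]]:
    """Greedy search for the stage-1 water-linewidth threshold.

    Starting from the threshold admitting the best-quartile (narrowest)
    shots, the threshold increases in ``step_hz`` steps; after each step the
    admitted shots are corrected, averaged and apodized, and the step is
    accepted iff the FA SNR is maintained or increased ("maintained" within
    the relative measurement tolerance ``snr_tol``; at equal SNR the step
    must not grow the FA linewidth).  Returns the last accepted threshold
    and the whole explored (threshold, SNR, LW) trace.
    """
    if len(shots) < 4:
        raise ValidationError("adaptive threshold needs at least 4 shots")
    lws = np.array([s.water_lw_hz for s in shots])
    finite = lws[np.isfinite(lws)]
    if finite.size == 0:
        raise ValidationError("no finite water linewidths")

    acq = series.acq.with_(n_shots=1, n_channels=1)
    # pooled single-shot noise floor: the SNR of an n-shot average is then
    # height * sqrt(n) / sigma_single, which varies smoothly with the
    # admitted set instead of re-estimating the noise floor at every step
    sigma_single = float(
        np.median(
            [
                noise_sd_spectrum(
                    to_spectrum(
                        apodize(series.data[i, 0, :], apodize_lb_hz, acq.dwell_s), acq
                    )
                )
                for i in range(series.n_shots)
            ]
        )
    )

    def eval_threshold(thr: float) -> tuple[float, float, int]:
        mask = np.isfinite(lws) & (lws <= thr)
        if not mask.any():
            return (-math.inf, math.inf, 0)
        n_adm = int(mask.sum())
        avg = _corrected_average(series, shots, mask, correct_phase=False)
        avg = apodize(avg, apodize_lb_hz, series.acq.dwell_s)
        sp = to_spectrum(avg, acq)
        win = sp.window(fa_ppm - 0.15, fa_ppm + 0.15)
        height = float(np.max(sp.values.real[win]))
        s = height * math.sqrt(n_adm) / sigma_single if sigma_single > 0 else math.inf
        try:
            lw = fwhm(sp, fa_ppm, 0.4)
        except ValidationError:
            lw = math.inf
        return (s, lw, n_adm)

    if start == "quartile":
        thr = float(np.percentile(finite, 25.0))
    elif start == "min":
        thr = float(finite.min()) + step_hz
    else:
        raise ValidationError("start must be 'quartile' or 'min'")

    cur_snr, cur_lw, cur_n = eval_threshold(thr)
    trace = [(thr, cur_snr, cur_lw)]
    best_thr = thr
    max_lw = float(finite.max())
    while best_thr <= max_lw:
        cand = best_thr + step_hz
        new_snr, new_lw, new_n = eval_threshold(cand)
        trace.append((cand, new_snr, new_lw))
        if new_n == cur_n:
            # membership unchanged; extend threshold only while shots remain
            if cand > max_lw:
                break
            best_thr = cand
            continue
        # accept while SNR is maintained (within tolerance of the running
        # best) or increased; at equal SNR prefer a smaller resulting FA LW
        if new_snr < cur_snr * (1.0 - snr_tol):
            break
        if new_snr == cur_snr and new_lw > cur_lw:
            break
        best_thr, cur_snr, cur_lw, cur_n = cand, max(new_snr, cur_snr), new_lw, new_n
    return best_thr, trace


# ---------------------------------------------------------------------------
# Stage 2: phase gate


def phase_gate(
    shots: list[ShotQC],
    k: float = 0.6,
    *,
    sd_over: str = "all",
) -> list[ShotQC]:
    """Reject shots whose water phase deviates > ``k x SD`` from the
    circular mean.

    The SD is estimated over the whole scan (every characterized shot) by
    default, or over current survivors with ``sd_over="accepted"``.  Only
    shots still accepted (stage-1 survivors) are evaluated for rejection.
    Zero phase variance rejects nothing.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    if sd_over == "all":
        pool = shots
    elif sd_over == "accepted":
        pool = [s for s in shots if s.accepted]
    else:
        raise ValidationError("sd_over must be 'all' or 'accepted'")
    phases = np.array([s.water_phase_rad for s in pool])
    mean = math.atan2(float(np.mean(np.sin(phases))), float(np.mean(np.cos(phases))))
    devs = wrap_phase(phases - mean)
    sd = float(np.std(devs))
    if sd == 0.0:
        return shots
    for s in shots:
        if s.accepted:
            dev = abs(float(wrap_phase(s.water_phase_rad - mean)))
            if dev > k * sd:
                s.reject("phase")
    return shots


# ---------------------------------------------------------------------------
# Full gate


def gate_and_average(
    series: FIDSeries,
    *,
    mode: str = "fb",
    k_phase: float = 0.6,
    lw_step_hz: float = 1.0,
    stage1_start: str = "quartile",
    sd_over: str = "all",
    disable: str = "none",
    shots: list[ShotQC] | None = None,
) -> GatingResult:
    """Run both gating stages and average the surviving shots.

    ``mode="bh"`` (breath-hold) disables both thresholds: every shot is
    used, but shots are still phase/frequency-corrected before averaging.
    ``disable`` switches off one stage ("lw" or "phase") in FB mode.
    """
    if shots is None:
        shots = characterize_shots(series)
    if len(shots) != series.n_shots:
        raise ValidationError("shots list does not match series")

    mode = mode.lower()
    trace: list[tuple[float, float, float]] = []
    thr = math.nan
    if mode == "bh":
        pass  # no gating: all shots used
    elif mode == "fb":
        if disable not in ("none", "lw", "phase"):
            raise ValidationError("disable must be 'none', 'lw' or 'phase'")
        if disable != "lw":
            thr, trace = auto_lw_threshold(
                shots, series, step_hz=lw_step_hz, start=stage1_start
            )
            for s in shots:
                if not np.isfinite(s.water_lw_hz) or s.water_lw_hz > thr:
                    s.reject("linewidth")
        if disable != "phase":
            phase_gate(shots, k_phase, sd_over=sd_over)
    else:
        raise ValidationError("mode must be 'bh' or 'fb'")

    mask = np.array([s.accepted for s in shots])
    if not mask.any():
        raise ValidationError("all shots rejected by gating")
    averaged = _corrected_average(series, shots, mask)

    n_lw = sum(1 for s in shots if s.reject_reason == "linewidth")
    n_ph = sum(1 for s in shots if s.reject_reason == "phase")
    result = GatingResult(
        lw_threshold_hz=thr,
        n_rejected_lw=n_lw,
        n_rejected_phase=n_ph,
        n_used=int(mask.sum()),
        averaged_fid=averaged,
        shots=shots,
        fa_snr_trace=trace,
    )
    assert result.n_shots == series.n_shots
    return result
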