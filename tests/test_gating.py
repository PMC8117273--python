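"""Retrospective gating: shot characterization, both stages, bookkeeping."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from cardiomrs import simulate
from cardiomrs.datamodel import AcquisitionParams, FIDSeries, ValidationError
from cardiomrs.fitting import component_fid
from cardiomrs.gating import (
    ShotQC,
    auto_lw_threshold,
    characterize_shots,
    gate_and_average,
    phase_gate,
)
from cardiomrs.preprocess import apodize, fwhm, snr, svd_combine, to_spectrum, zero_fill


def _wrap(x):
    return np.angle(np.exp(1j * np.asarray(x)))


def _combined_fb(seed=1, **kw):
    scen = simulate.invivo_scenario("fb", seed=seed, **kw)
    series, truth = simulate.simulate_series(scen)
    return svd_combine(series), truth


def _qc(phases, lws=None):
    lws = lws if lws is not None else [15.0] * len(phases)
    return [
        ShotQC(
            shot=i,
            water_amp=1.0,
            water_lw_hz=lws[i],
            water_shift_hz=0.0,
            water_phase_rad=p,
        )
        for i, p in enumerate(phases)
    ]


# ---------------------------------------------------------------------------
# characterization


def test_characterization_recovers_simulated_draws():
    combined, truth = _combined_fb(seed=1)
    qc = characterize_shots(combined)
    ph = np.array([s.water_phase_rad for s in qc])
    sh = np.array([s.water_shift_hz for s in qc])
    r_ph = np.corrcoef(
        _wrap(ph - np.median(ph)), _wrap(truth.phase_rad - np.median(truth.phase_rad))
    )[0, 1]
    r_sh = np.corrcoef(sh, truth.freq_offset_hz)[0, 1]
    assert r_ph > 0.99
    assert r_sh > 0.99


def test_unperturbed_shots_give_identical_qc_rows():
    scen = simulate.invivo_scenario(
        "bh", seed=0, n_shots=4, n_channels=1, noise_sd=0.0
    ).replace(breathing=simulate.Breathing())
    series, _ = simulate.simulate_series(scen)
    qc = characterize_shots(series)
    for s in qc[1:]:
        assert s.water_amp == pytest.approx(qc[0].water_amp)
        assert s.water_lw_hz == pytest.approx(qc[0].water_lw_hz)
        assert s.water_phase_rad == pytest.approx(qc[0].water_phase_rad)


def test_broadened_shot_has_maximum_linewidth():
    acq = AcquisitionParams(n_points=1024, n_shots=5, n_channels=1)
    t = acq.time_axis_s
    base = component_fid(4.7, 12.0, "lorentzian", acq)
    data = np.repeat(base[None, None, :], 5, axis=0).astype(complex)
    data[3, 0, :] *= np.exp(-np.pi * 36.0 * t)  # 3x linewidth jitter
    qc = characterize_shots(FIDSeries(data=data, acq=acq))
    lws = [s.water_lw_hz for s in qc]
    assert int(np.argmax(lws)) == 3


def test_no_water_peak_raises_helpful_error(rng):
    acq = AcquisitionParams(n_points=1024, n_shots=6, n_channels=1)
    data = 1e-3 * (
        rng.normal(size=(6, 1, 1024)) + 1j * rng.normal(size=(6, 1, 1024))
    )
    with pytest.raises(ValidationError, match="non-suppressed"):
        characterize_shots(FIDSeries(data=data, acq=acq))


# ---------------------------------------------------------------------------
# stage 1: adaptive linewidth threshold


def test_identical_shots_threshold_admits_all():
    scen = simulate.invivo_scenario(
        "fb", seed=0, n_shots=12, n_channels=1, noise_sd=1e-4
    ).replace(breathing=simulate.Breathing())
    series, _ = simulate.simulate_series(scen)
    qc = characterize_shots(series)
    thr, trace = auto_lw_threshold(qc, series)
    lws = [s.water_lw_hz for s in qc]
    assert thr >= max(lws)
    assert len(trace) >= 1


def test_threshold_excludes_corrupted_shots():
    scen = simulate.invivo_scenario(
        "fb", seed=4, n_shots=100, n_channels=1, corrupt_fraction=0.2
    )
    series, truth = simulate.simulate_series(scen)
    qc = characterize_shots(series)
    thr, _ = auto_lw_threshold(qc, series)
    lws = np.array([s.water_lw_hz for s in qc])
    rejected = ~(np.isfinite(lws) & (lws <= thr))
    corrupted = truth.corrupted
    frac_bad_rejected = rejected[corrupted].mean()
    frac_clean_rejected = rejected[~corrupted].mean()
    assert frac_bad_rejected >= 0.8
    assert frac_clean_rejected <= 0.1


def test_trace_is_recorded_and_final_snr_is_running_max():
    combined, _ = _combined_fb(seed=2)
    qc = characterize_shots(combined)
    thr, trace = auto_lw_threshold(qc, combined)
    assert len(trace) >= 2
    accepted_snrs = [s for t, s, _ in trace if t <= thr and math.isfinite(s)]
    final = [s for t, s, _ in trace if t == thr][0]
    # the returned threshold's SNR sits at (or within tolerance of) the
    # running maximum over accepted steps
    assert final >= 0.98 * max(accepted_snrs)


def test_threshold_needs_at_least_four_shots():
    combined, _ = _combined_fb(seed=2)
    qc = characterize_shots(combined)
    with pytest.raises(ValidationError):
        auto_lw_threshold(qc[:3], combined)


# ---------------------------------------------------------------------------
# stage 2: phase gate


def test_equal_phases_reject_nothing():
    shots = phase_gate(_qc([0.3] * 10))
    assert all(s.accepted for s in shots)


def test_single_phase_outlier_rejected():
    shots = phase_gate(_qc([0.0, 0.0, 0.0, 0.0, np.pi / 2]))
    rejected = [s.shot for s in shots if not s.accepted]
    assert rejected == [4]
    assert shots[4].reject_reason == "phase"


def test_gaussian_phase_rejection_fraction_matches_tail_probability(rng):
    phases = rng.normal(0.0, 0.4, 10_000)
    shots = phase_gate(_qc(phases), k=0.6)
    frac = np.mean([not s.accepted for s in shots])
    expected = 2 * (1 - norm.cdf(0.6))  # 0.5485
    assert frac == pytest.approx(expected, abs=0.02)


def test_phase_gate_k_extremes(rng):
    phases = rng.normal(0.0, 0.4, 50)
    assert all(s.accepted for s in phase_gate(_qc(phases), k=1e9))
    shots = phase_gate(_qc(phases), k=0.0)
    # k = 0 rejects every shot with nonzero deviation from the mean
    devs = np.abs(_wrap(phases - np.angle(np.mean(np.exp(1j * phases)))))
    assert sum(not s.accepted for s in shots) == int(np.sum(devs > 0))


def test_phase_gate_only_evaluates_stage1_survivors():
    shots = _qc([0.0, 0.0, 0.0, 0.0, 1.5, -1.5])
    shots[4].reject("linewidth")
    phase_gate(shots, k=0.6)
    assert shots[4].reject_reason == "linewidth"  # untouched by stage 2
    assert not shots[5].accepted and shots[5].reject_reason == "phase"


# ---------------------------------------------------------------------------
# full gate


def test_bookkeeping_identity_and_counts():
    combined, _ = _combined_fb(seed=3)
    res = gate_and_average(combined, mode="fb")
    assert res.n_used + res.n_rejected_lw + res.n_rejected_phase == combined.n_shots
    assert res.n_used >= 1


def test_bh_mode_uses_every_shot():
    scen = simulate.invivo_scenario("bh", seed=5, n_channels=2)
    series, _ = simulate.simulate_series(scen)
    res = gate_and_average(svd_combine(series), mode="bh")
    assert res.n_used == 8
    assert res.n_rejected_lw == 0 and res.n_rejected_phase == 0
    assert math.isnan(res.lw_threshold_hz)


def test_averaging_gains_snr_over_single_shot():
    combined, _ = _combined_fb(seed=6)
    res = gate_and_average(combined, mode="fb")
    acq = combined.acq.with_(n_shots=1)

    def fa_snr(fid):
        proc = apodize(fid, 10.0, acq.dwell_s)
        return snr(to_spectrum(proc, acq), 1.3)

    accepted = [i for i, s in enumerate(res.shots) if s.accepted]
    singles = [fa_snr(combined.data[i, 0, :]) for i in accepted[:10]]
    assert fa_snr(res.averaged_fid) >= 0.8 * math.sqrt(res.n_used) * np.mean(singles)


def test_gating_reduces_linewidth_and_amplitude_bias_on_corrupted_series():
    scen = simulate.invivo_scenario(
        "fb", seed=7, n_shots=100, n_channels=1, corrupt_fraction=0.2
    )
    series, truth = simulate.simulate_series(scen)
    gated = gate_and_average(series, mode="fb")
    ungated = gate_and_average(series, mode="bh")
    acq = series.acq.with_(n_shots=1)

    def water_lw(fid):
        proc = apodize(zero_fill(fid, 2), 10.0, acq.dwell_s)
        return fwhm(to_spectrum(proc, acq.with_(n_points=proc.size)), 4.7, 0.5)

    grid_hz = 1.0 / (2 * acq.n_points * acq.dwell_s)
    assert water_lw(gated.averaged_fid) <= water_lw(ungated.averaged_fid) + grid_hz

    def fa_height(fid):
        spec = to_spectrum(apodize(fid, 10.0, acq.dwell_s), acq)
        return np.max(spec.values.real[spec.window(1.15, 1.45)])

    clean = simulate.simulate_series(scen.replace(corrupt_fraction=0.0, noise_sd=0.0,
                                                  breathing=simulate.Breathing()))[0]
    ref = fa_height(clean.data[0, 0, :])
    bias_gated = abs(fa_height(gated.averaged_fid) - ref)
    bias_ungated = abs(fa_height(ungated.averaged_fid) - ref)
    assert bias_gated <= bias_ungated


def test_all_rejected_is_explicit_error():
    combined, _ = _combined_fb(seed=3, n_shots=10)
    shots = characterize_shots(combined)
    for s in shots:
        s.reject("linewidth")
    with pytest.raises(ValidationError, match="rejected"):
        gate_and_average(combined, mode="bh", shots=shots)
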