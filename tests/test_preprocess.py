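"""Phasing, coil combination, zero-fill/apodization, realignment, metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiomrs.datamodel import AcquisitionParams, FIDSeries, Spectrum, ValidationError
from cardiomrs.fitting import component_fid
from cardiomrs.preprocess import (
    SpectralMetrics,
    apodize,
    autophase,
    compute_metrics,
    from_spectrum,
    fwhm,
    qc_filter,
    realign_shots,
    snr,
    svd_combine,
    to_spectrum,
    zero_fill,
)


def _lorentz_fid(acq, ppm=3.0, lw=10.0, amp=1.0):
    return amp * component_fid(ppm, lw, "lorentzian", acq)


# ---------------------------------------------------------------------------
# autophase


def test_autophase_recovers_constant_phase(acq_small):
    fid = _lorentz_fid(acq_small)
    rotated = fid * np.exp(1j * 0.7)
    corrected, est = autophase(rotated, acq_small)
    assert est.phi0_rad == pytest.approx(0.7, abs=1e-3)
    # corrected FID matches the unrotated original to the phase tolerance
    np.testing.assert_allclose(corrected, fid, atol=1e-3 * np.abs(fid).max())


def test_autophase_is_idempotent(acq_small):
    fid = _lorentz_fid(acq_small) * np.exp(1j * 1.1)
    once, _ = autophase(fid, acq_small)
    twice, est2 = autophase(once, acq_small)
    assert abs(est2.phi0_rad) < 1e-6
    assert abs(est2.phi1_rad_per_hz) < 1e-8


def test_autophase_recovers_linear_phase_of_delayed_fid(acq_small):
    # two well-separated narrow lines pin down the frequency-linear slope
    fid = _lorentz_fid(acq_small, ppm=4.7, lw=6.0) + _lorentz_fid(
        acq_small, ppm=0.5, lw=6.0
    )
    delayed = np.concatenate([[0.0], fid[:-1]])
    _, est = autophase(delayed, acq_small)
    expected = 2 * np.pi * acq_small.dwell_s
    assert abs(est.phi1_rad_per_hz) == pytest.approx(expected, rel=0.05)


def test_autophase_rejects_zero_fid(acq_small):
    with pytest.raises(ValidationError):
        autophase(np.zeros(acq_small.n_points, dtype=complex), acq_small)


# ---------------------------------------------------------------------------
# svd_combine


def _series(acq, data):
    return FIDSeries(data=data, acq=acq)


def test_svd_single_channel_is_identity_up_to_phase(rng):
    acq = AcquisitionParams(n_points=256, n_shots=3, n_channels=1)
    fid = _lorentz_fid(acq)
    data = np.stack([fid[None, :]] * 3)
    out = svd_combine(_series(acq, data))
    ratio = out.data[0, 0] / fid
    np.testing.assert_allclose(np.abs(ratio), 1.0, atol=1e-9)
    assert np.std(np.angle(ratio)) < 1e-9


def test_svd_degenerate_second_channel(rng):
    acq = AcquisitionParams(n_points=256, n_shots=2, n_channels=2)
    fid = _lorentz_fid(acq)
    data = np.zeros((2, 2, 256), dtype=complex)
    data[:, 0, :] = fid
    out = svd_combine(_series(acq, data))
    # output equals channel 1 up to a phase, to near machine precision
    ratio = out.data[0, 0] / fid
    np.testing.assert_allclose(np.abs(ratio), 1.0, atol=1e-10)


def test_svd_combination_gains_sqrt2_for_two_equal_channels(rng):
    # matched-filter theory: two equal-gain channels with independent noise
    acq = AcquisitionParams(n_points=256, n_shots=1, n_channels=2)
    fid = _lorentz_fid(acq, amp=1.0, lw=20.0)
    gains = np.array([1.0, 1.0], dtype=complex)
    sigma = 0.02
    ratios = []
    for _ in range(200):
        noise = sigma * (
            rng.normal(size=(1, 2, 256)) + 1j * rng.normal(size=(1, 2, 256))
        )
        data = gains[None, :, None] * fid[None, None, :] + noise
        series = _series(acq, data)
        combined = svd_combine(series)
        acq1 = acq.with_(n_channels=1)
        s_comb = snr(to_spectrum(combined.data[0, 0], acq1), 3.0)
        s_single = snr(to_spectrum(data[0, 0], acq1), 3.0)
        ratios.append(s_comb / s_single)
    assert np.mean(ratios) == pytest.approx(math.sqrt(2.0), rel=0.10)


def test_svd_not_worse_than_best_single_channel(rng):
    # over random coil configurations the combined SNR must not fall below
    # the best channel (up to one Monte-Carlo SD)
    acq = AcquisitionParams(n_points=256, n_shots=2, n_channels=3)
    fid = _lorentz_fid(acq, lw=20.0)
    acq1 = acq.with_(n_channels=1)
    deficits = []
    for _ in range(30):
        gains = rng.normal(size=3) * np.exp(1j * rng.uniform(0, 2 * np.pi, 3))
        noise = 0.02 * (
            rng.normal(size=(2, 3, 256)) + 1j * rng.normal(size=(2, 3, 256))
        )
        data = gains[None, :, None] * fid[None, None, :] + noise
        combined = svd_combine(_series(acq, data))
        avg = combined.data[:, 0, :].mean(axis=0)
        s_comb = snr(to_spectrum(avg, acq1), 3.0)
        s_best = max(
            snr(to_spectrum(data[:, c, :].mean(axis=0), acq1), 3.0) for c in range(3)
        )
        deficits.append(s_comb / s_best - 1.0)
    mean, sd = np.mean(deficits), np.std(deficits)
    assert mean > -sd


# ---------------------------------------------------------------------------
# zero_fill / apodize


def test_zero_fill_factor_one_is_identity(acq_small, rng):
    fid = rng.normal(size=64) + 1j * rng.normal(size=64)
    np.testing.assert_array_equal(zero_fill(fid, 1), fid)


def test_zero_fill_preserves_original_grid_dft(rng):
    fid = rng.normal(size=512) + 1j * rng.normal(size=512)
    orig = np.fft.fft(fid)
    padded = np.fft.fft(zero_fill(fid, 2))
    np.testing.assert_allclose(padded[::2], orig, atol=1e-12 * np.abs(orig).max())


@given(st.integers(min_value=-3, max_value=0))
def test_zero_fill_invalid_factor_rejected(factor):
    with pytest.raises(ValidationError):
        zero_fill(np.ones(8, dtype=complex), factor)


def test_zero_fill_of_zeros_is_zeros():
    out = zero_fill(np.zeros(16, dtype=complex), 3)
    assert out.size == 48 and not np.any(out)


def test_apodize_zero_lb_is_identity_and_t0_unchanged(acq_small, rng):
    fid = rng.normal(size=128) + 1j * rng.normal(size=128)
    np.testing.assert_array_equal(apodize(fid, 0.0, acq_small.dwell_s), fid)
    out = apodize(fid, 10.0, acq_small.dwell_s)
    assert out[0] == fid[0]  # exp(0) = 1


def test_apodize_adds_lorentzian_linewidth():
    acq = AcquisitionParams(n_points=2048, n_shots=1, n_channels=1)
    fid = _lorentz_fid(acq, lw=10.0)
    out = apodize(fid, 10.0, acq.dwell_s)
    acq4 = acq.with_(n_points=acq.n_points * 4)
    spec = to_spectrum(zero_fill(out, 4), acq4)
    grid_hz = 1.0 / (acq4.n_points * acq4.dwell_s)
    assert fwhm(spec, 3.0, 0.5) == pytest.approx(20.0, abs=grid_hz)


def test_apodize_negative_lb_rejected(acq_small):
    with pytest.raises(ValidationError):
        apodize(np.ones(8, dtype=complex), -1.0, acq_small.dwell_s)


# ---------------------------------------------------------------------------
# realignment


def test_realign_recovers_imposed_shifts():
    acq = AcquisitionParams(n_points=2048, n_shots=3, n_channels=1)
    base = _lorentz_fid(acq, ppm=3.0, lw=8.0) + _lorentz_fid(acq, ppm=1.3, lw=15.0)
    t = acq.time_axis_s
    shifts = [4.0, -4.0, 0.0]
    data = np.stack([(base * np.exp(2j * np.pi * s * t))[None, :] for s in shifts])
    res = realign_shots(FIDSeries(data=data, acq=acq))
    rec = res.shifts_hz - res.shifts_hz[2]  # relative to the unshifted shot
    np.testing.assert_allclose(rec, shifts, atol=0.2)
    # aligned peak positions agree within one zero-filled grid step
    acq4 = acq.with_(n_points=acq.n_points * 4)
    peaks = [
        to_spectrum(zero_fill(res.series.data[i, 0], 4), acq4).ppm_axis[
            np.argmax(np.abs(to_spectrum(zero_fill(res.series.data[i, 0], 4), acq4).values))
        ]
        for i in range(3)
    ]
    grid_ppm = (1.0 / (acq4.n_points * acq4.dwell_s)) / acq4.f0_mhz
    assert max(peaks) - min(peaks) <= grid_ppm + 1e-12


def test_realign_identical_shots_zero_shifts():
    acq = AcquisitionParams(n_points=512, n_shots=4, n_channels=1)
    base = _lorentz_fid(acq)
    data = np.repeat(base[None, None, :], 4, axis=0)
    res = realign_shots(FIDSeries(data=data, acq=acq))
    np.testing.assert_allclose(res.shifts_hz, 0.0, atol=1e-9)


def test_realign_flags_pure_noise_low_confidence(rng):
    acq = AcquisitionParams(n_points=512, n_shots=8, n_channels=1)
    data = rng.normal(size=(8, 1, 512)) + 1j * rng.normal(size=(8, 1, 512))
    res = realign_shots(FIDSeries(data=data, acq=acq))
    assert res.low_confidence.all()


def test_realign_never_increases_peak_position_spread(rng):
    acq = AcquisitionParams(n_points=1024, n_shots=6, n_channels=1)
    t = acq.time_axis_s
    base = _lorentz_fid(acq, ppm=3.0, lw=10.0)
    data = np.stack(
        [
            (
                base * np.exp(2j * np.pi * rng.normal(0, 3.0) * t)
                + 0.01 * (rng.normal(size=1024) + 1j * rng.normal(size=1024))
            )[None, :]
            for _ in range(6)
        ]
    )
    series = FIDSeries(data=data, acq=acq)

    def peak_sd(s):
        pos = []
        for i in range(s.n_shots):
            spec = to_spectrum(s.data[i, 0], acq)
            pos.append(spec.ppm_axis[np.argmax(np.abs(spec.values))])
        return np.std(pos)

    res = realign_shots(series)
    assert peak_sd(res.series) <= peak_sd(series) + 1e-12


# ---------------------------------------------------------------------------
# spectrum, fwhm, snr, qc


def test_spectrum_roundtrip(acq_small, rng):
    fid = rng.normal(size=512) + 1j * rng.normal(size=512)
    back = from_spectrum(to_spectrum(fid, acq_small))
    np.testing.assert_allclose(back, fid, atol=1e-12)


def test_zero_fid_gives_zero_spectrum(acq_small):
    spec = to_spectrum(np.zeros(512, dtype=complex), acq_small)
    assert not np.any(spec.values)


def test_fwhm_lorentzian_closed_form():
    acq = AcquisitionParams(n_points=4096, n_shots=1, n_channels=1)
    fid = _lorentz_fid(acq, ppm=3.0, lw=15.0)
    acq4 = acq.with_(n_points=acq.n_points * 4)
    spec = to_spectrum(zero_fill(fid, 4), acq4)
    grid_hz = 1.0 / (acq4.n_points * acq4.dwell_s)
    assert fwhm(spec, 3.0, 0.5) == pytest.approx(15.0, abs=grid_hz)


def test_fwhm_gaussian_closed_form():
    acq = AcquisitionParams(n_points=4096, n_shots=1, n_channels=1)
    fid = component_fid(3.0, 22.0, "gaussian", acq)
    acq4 = acq.with_(n_points=acq.n_points * 4)
    spec = to_spectrum(zero_fill(fid, 4), acq4)
    grid_hz = 1.0 / (acq4.n_points * acq4.dwell_s)
    assert fwhm(spec, 3.0, 0.5) == pytest.approx(22.0, abs=grid_hz)


def test_fwhm_flat_spectrum_rejected(acq_small):
    ppm = np.linspace(10, -5, 256)
    spec = Spectrum(values=np.ones(256, dtype=complex), ppm_axis=ppm, hz_per_ppm=123.2)
    with pytest.raises(ValidationError):
        fwhm(spec, 3.0, 0.5)


def test_snr_constructed_values():
    ppm = np.linspace(10, -5, 1501)
    values = np.zeros(1501, dtype=complex)
    noise_mask = (ppm >= -3) & (ppm <= -1)
    # alternate +2/-2 in the noise window -> SD ~= 2
    idx = np.flatnonzero(noise_mask)
    values[idx] = np.where(np.arange(idx.size) % 2 == 0, 2.0, -2.0)
    values[np.argmin(np.abs(ppm - 3.0))] = 10.0
    spec = Spectrum(values=values, ppm_axis=ppm, hz_per_ppm=123.2)
    sd = np.std(values[noise_mask].real, ddof=1)
    assert snr(spec, 3.0) == pytest.approx(10.0 / sd, rel=1e-12)


def test_snr_noiseless_guard_returns_inf():
    ppm = np.linspace(10, -5, 301)
    values = np.zeros(301, dtype=complex)
    values[np.argmin(np.abs(ppm - 3.0))] = 5.0
    spec = Spectrum(values=values, ppm_axis=ppm, hz_per_ppm=123.2)
    assert snr(spec, 3.0) == math.inf


def test_qc_rules_and_boundaries():
    ok = SpectralMetrics(water_lw_hz=20.0, peak_snr={"Cr": 12.0, "FA": 43.0}, noise_sd=1.0)
    assert qc_filter(ok) == (True, [])
    bad_lw = SpectralMetrics(water_lw_hz=36.0, peak_snr={"Cr": 12.0}, noise_sd=1.0)
    passed, reasons = qc_filter(bad_lw)
    assert not passed and any("linewidth" in r for r in reasons)
    # strict inequalities: exactly 35 Hz and exactly SNR 5 both pass
    edge = SpectralMetrics(water_lw_hz=35.0, peak_snr={"Cr": 5.0}, noise_sd=1.0)
    assert qc_filter(edge) == (True, [])
    low_snr = SpectralMetrics(water_lw_hz=20.0, peak_snr={"FA": 4.9}, noise_sd=1.0)
    passed, reasons = qc_filter(low_snr)
    assert not passed and any("snr" in r for r in reasons)


def test_compute_metrics_on_synthetic_spectrum(rng):
    acq = AcquisitionParams(n_points=2048, n_shots=1, n_channels=1)
    fid = (
        _lorentz_fid(acq, ppm=4.7, lw=18.0, amp=1.0)
        + _lorentz_fid(acq, ppm=3.027, lw=6.0, amp=0.2)
        + component_fid(1.3, 25.0, "gaussian", acq) * 0.5
        + 0.001 * (rng.normal(size=2048) + 1j * rng.normal(size=2048))
    )
    m = compute_metrics(to_spectrum(fid, acq))
    assert m.qc_pass
    assert m.water_lw_hz == pytest.approx(18.0, abs=2.0)
    assert m.peak_snr["Cr"] > 5 and m.peak_snr["FA"] > 5
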