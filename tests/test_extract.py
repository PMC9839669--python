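"""ECG extraction chain: each stage against constructed signals."""

import numpy as np
import pytest

from hrvreact.core import BeatSeries, Waveform
from hrvreact.extract import (
    CleanRules,
    SpectralEstimate,
    bandpass_qrs,
    beat_detection_scores,
    beats_to_rr,
    clean_rr,
    detect_noise_peaks,
    detect_qrs,
    detrend,
    estimate_spectrum,
    flatten_noise_band,
    isolate_ecg_pca,
    select_channel,
)
from hrvreact.simulate import beat_times_from_rr, contaminate, synthesize_ecg

from conftest import rr_from_intervals


def _tone(freq, fs=1000.0, dur=30.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return Waveform(amp * np.sin(2 * np.pi * freq * t), fs)


# --------------------------------------------------------------------- detrend


def test_detrend_removes_mean_and_trend():
    w = Waveform(np.full(100, 5.0), 100.0)
    assert np.allclose(detrend(w).samples, 0.0)
    w2 = Waveform(np.array([1.0, -1.0]), 100.0)
    assert np.allclose(detrend(w2).samples, [1.0, -1.0])
    ramp = Waveform(np.linspace(0, 1, 1000), 100.0)
    resid = detrend(ramp, linear=True).samples
    slope = np.polyfit(np.arange(1000), resid, 1)[0]
    assert abs(slope) < 1e-9
    with pytest.raises(ValueError):
        detrend(Waveform(np.array([1.0]), 100.0))


# ---------------------------------------------------------------- noise peaks


def test_noise_peak_detection_on_constructed_spectra():
    f = np.arange(0.0, 200.0, 0.1)
    flat = SpectralEstimate(f, np.ones_like(f))
    assert detect_noise_peaks(flat, [50.0, 100.0]) == []
    peaked = np.ones_like(f)
    peaked[(f >= 49.5) & (f < 50.5)] = 50.0
    spec = SpectralEstimate(f, peaked)
    assert detect_noise_peaks(spec, [50.0, 100.0]) == [(49.5, 50.5)]
    assert detect_noise_peaks(spec, [50.0], threshold=np.inf) == []
    with pytest.warns(UserWarning, match="beyond"):
        out = detect_noise_peaks(spec, [500.0])
    assert out == []


def test_noise_peak_detected_from_real_tone():
    rng = np.random.default_rng(0)
    w = _tone(50.0, amp=1.0)
    w = Waveform(w.samples + 0.01 * rng.standard_normal(w.n), w.fs)
    spec = estimate_spectrum(w)
    assert (49.5, 50.5) in detect_noise_peaks(spec, [50.0, 100.0, 150.0])


# ------------------------------------------------------------------ flattening


def test_flatten_noise_band_equalises_band_power():
    rng = np.random.default_rng(1)
    fs = 1000.0
    x = rng.standard_normal(60_000)
    t = np.arange(x.size) / fs
    x = x + 5.0 * np.sin(2 * np.pi * 50.0 * t)
    w = Waveform(x, fs)
    out = flatten_noise_band(w, (49.5, 50.5))
    # recompute the periodogram of the output signal
    X = np.fft.rfft(out.samples)
    f = np.fft.rfftfreq(out.n, 1 / fs)
    band = float(np.mean(np.abs(X[(f >= 49.5) & (f < 50.5)]) ** 2))
    flank_sel = ((f >= 49.0) & (f < 49.5)) | ((f >= 50.5) & (f < 51.0))
    flank = float(np.mean(np.abs(X[flank_sel]) ** 2))
    assert band == pytest.approx(flank, rel=0.05)
    # a segment-averaged estimate agrees within its own variance
    spec = estimate_spectrum(out, resolution_hz=0.125)
    welch_band = spec.band_mean(49.5, 50.5)
    welch_flank = 0.5 * (spec.band_mean(49.0, 49.5) + spec.band_mean(50.5, 51.0))
    assert welch_band == pytest.approx(welch_flank, rel=0.2)


def test_flatten_conserves_out_of_band_power():
    rng = np.random.default_rng(2)
    w = Waveform(rng.standard_normal(30_000), 1000.0)
    out = flatten_noise_band(w, (49.5, 50.5))
    X_in = np.fft.rfft(w.samples)
    X_out = np.fft.rfft(out.samples)
    f = np.fft.rfftfreq(w.n, 1 / w.fs)
    outside = (f < 49.5) | (f >= 50.5)
    p_in = float(np.sum(np.abs(X_in[outside]) ** 2))
    p_out = float(np.sum(np.abs(X_out[outside]) ** 2))
    assert p_out == pytest.approx(p_in, rel=1e-6)


def test_flatten_noop_and_idempotence():
    rng = np.random.default_rng(3)
    w = Waveform(rng.standard_normal(30_000), 1000.0)
    once = flatten_noise_band(w, (49.5, 50.5))
    twice = flatten_noise_band(once, (49.5, 50.5))

    def band_power(wave):
        X = np.fft.rfft(wave.samples)
        f = np.fft.rfftfreq(wave.n, 1 / wave.fs)
        return float(np.mean(np.abs(X[(f >= 49.5) & (f < 50.5)]) ** 2))

    assert band_power(twice) == pytest.approx(band_power(once), rel=0.05)
    with pytest.raises(ValueError):
        flatten_noise_band(w, (0.2, 1.2))
    with pytest.raises(ValueError):
        flatten_noise_band(w, (499.2, 499.9))


# -------------------------------------------------------------------- bandpass


def test_bandpass_gains():
    inb = bandpass_qrs(_tone(25.0))
    mid = inb.samples[5000:25000]
    assert 0.9 <= np.max(np.abs(mid)) <= 1.0
    out50 = bandpass_qrs(_tone(50.0))
    assert np.max(np.abs(out50.samples[5000:25000])) < np.max(np.abs(mid))
    dc = bandpass_qrs(Waveform(np.full(10_000, 3.0), 1000.0))
    assert abs(np.mean(dc.samples)) < 1e-6
    with pytest.raises(ValueError):
        bandpass_qrs(Waveform(np.zeros(100), 80.0))


# ------------------------------------------------------------------------- PCA


def test_pca_preserves_clean_qrs_train(clean_ecg):
    bp = bandpass_qrs(clean_ecg)
    r25 = np.corrcoef(isolate_ecg_pca(bp, 25).samples, bp.samples)[0, 1]
    assert r25 > 0.95
    r_default = np.corrcoef(isolate_ecg_pca(bp).samples, bp.samples)[0, 1]
    assert r_default > 0.9


def test_pca_improves_qrs_band_snr(clean_ecg):
    """EMG-band noise at 0 dB QRS-band SNR: the learned rank-1 operator,
    applied separately to the signal and noise components, raises the
    10-40 Hz band SNR."""
    from hrvreact.simulate import SimulationConfig, _band_power

    cfg = SimulationConfig(mains_amplitude_mv=0.0, drift_amplitude_mv=0.0)
    dirty = contaminate(clean_ecg, cfg, 4)
    fs = clean_ecg.fs
    bp_clean = bandpass_qrs(clean_ecg).samples
    bp_dirty = bandpass_qrs(dirty).samples
    noise = bp_dirty - bp_clean
    snr_in = _band_power(bp_clean, fs, 10, 40) / _band_power(noise, fs, 10, 40)

    embed = int(round(0.080 * fs))
    X = np.lib.stride_tricks.sliding_window_view(bp_dirty, embed)
    _, evecs = np.linalg.eigh(X.T @ X)
    w = evecs[:, -1]

    def rank1(x):
        Xx = np.lib.stride_tricks.sliding_window_view(x, embed)
        counts = np.convolve(np.ones(x.size - embed + 1), np.ones(embed))
        return np.convolve(Xx @ w, w) / counts

    snr_out = _band_power(rank1(bp_clean), fs, 10, 40) / _band_power(
        rank1(noise), fs, 10, 40
    )
    assert snr_in < 1.5  # the scenario really is near 0 dB
    assert snr_out > snr_in


def test_pca_on_noise_contracts_variance():
    rng = np.random.default_rng(5)
    w = Waveform(rng.standard_normal(20_000), 1000.0)
    out = isolate_ecg_pca(w)
    assert np.var(out.samples) <= np.var(w.samples)
    with pytest.raises(ValueError):
        isolate_ecg_pca(Waveform(np.zeros(10), 1000.0), embed_dim=50)


# ------------------------------------------------------------------- detection


def test_detect_qrs_on_clean_60bpm_minute():
    beats = BeatSeries(np.arange(0.5, 60.0, 1.0))
    wave = synthesize_ecg(beats, 1000.0, duration_s=60.0)
    found = detect_qrs(isolate_ecg_pca(bandpass_qrs(wave)))
    assert abs(found.n - beats.n) <= 1
    scores = beat_detection_scores(beats.beat_times_s, found.beat_times_s)
    assert scores["sensitivity"] >= 0.98
    assert scores["median_beat_err_s"] <= 0.005


def test_detect_qrs_zero_phase_filtering_shift(clean_ecg, clean_rr):
    truth = beat_times_from_rr(clean_rr)
    found = detect_qrs(isolate_ecg_pca(bandpass_qrs(clean_ecg)))
    scores = beat_detection_scores(truth, found.beat_times_s)
    assert scores["median_beat_err_s"] < 0.002


def test_detect_qrs_flat_and_refractory():
    with pytest.warns(UserWarning):
        empty = detect_qrs(Waveform(np.zeros(5000), 1000.0))
    assert empty.n == 0
    # two template deflections 100 ms apart -> a single detection
    t = np.arange(3000) / 1000.0
    x = np.zeros_like(t)
    for tb in (1.0, 1.1):
        sig = 0.08 / 6.0
        u = ((t - tb) / sig) ** 2
        x += (1 - u) * np.exp(-u / 2)
    found = detect_qrs(Waveform(x, 1000.0), rhythm_refine=False)
    assert found.n == 1


# ------------------------------------------------------------------ RR cleanup


def test_beats_to_rr():
    rr = beats_to_rr(BeatSeries(np.array([1.0, 2.0, 3.5])))
    assert np.allclose(rr.intervals_s, [1.0, 1.5])
    assert np.allclose(rr.interval_end_times_s, [2.0, 3.5])
    assert beats_to_rr(BeatSeries(np.array([1.0]))).n == 0
    with pytest.raises(ValueError):
        BeatSeries(np.array([2.0, 1.0]))


def test_clean_rr_rules():
    ok = rr_from_intervals(np.full(20, 0.8))
    assert int(clean_rr(ok).flags.sum()) == 0
    x = np.full(21, 0.8)
    x[10] = 0.1
    rr = rr_from_intervals(x)
    flags = clean_rr(rr).flags
    assert flags[10] == 1 and flags.sum() == 1
    disabled = clean_rr(rr, CleanRules(enabled=False))
    assert int(disabled.flags.sum()) == 0
    # accepted values are never modified
    assert np.array_equal(clean_rr(rr).intervals_s, rr.intervals_s)


def test_select_channel(clean_ecg):
    rng = np.random.default_rng(6)
    noise = Waveform(rng.standard_normal(clean_ecg.n) * 0.5, clean_ecg.fs)
    short_ecg = Waveform(clean_ecg.samples[:120_000], clean_ecg.fs)
    short_noise = Waveform(noise.samples[:120_000], noise.fs)
    assert select_channel([short_ecg]) == 0
    assert select_channel([short_noise, short_ecg]) == 1
    assert select_channel([short_ecg, short_ecg]) == 0
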