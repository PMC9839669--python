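"""Synthetic cohort generator: determinism, calibration, ranges."""

import numpy as np
import pytest

from hrvreact.core import BeatSeries
from hrvreact.metrics import mean_hr, rmssd, sdnn, window_rr
from hrvreact.simulate import (
    CONTROL_CALIBRATION,
    FM_CALIBRATION,
    AutonomicProfile,
    EcgTemplate,
    SimulationConfig,
    beat_times_from_rr,
    build_profile,
    contaminate,
    generate_cohort,
    generate_nrs_ratings,
    generate_rr_trajectory,
    generate_subject,
    largest_remainder_allocation,
    synthesize_ecg,
)

from conftest import PHASES, flat_profile


def test_zero_variability_profile_gives_constant_rr(schedule):
    rr = generate_rr_trajectory(flat_profile(60.0), schedule, 0)
    assert np.allclose(rr.intervals_s, 1.0)
    assert rmssd(rr) == 0.0 and sdnn(rr) == 0.0
    # beats cover the recording
    assert rr.interval_end_times_s[-1] >= schedule.end_s - 1.5


def test_trajectory_deterministic_under_seed(schedule, default_cfg):
    prof = build_profile("FM", 3, default_cfg, np.random.default_rng(5))
    a = generate_rr_trajectory(prof, schedule, 99)
    b = generate_rr_trajectory(prof, schedule, 99)
    assert np.array_equal(a.intervals_s, b.intervals_s)
    c = generate_rr_trajectory(prof, schedule, 100)
    assert not np.array_equal(a.intervals_s, c.intervals_s)


def test_fm_profile_hr_rise_matches_group_calibration(schedule):
    """Group-mean HR rises baseline -> stress1 by roughly 10.6 bpm."""
    prof = AutonomicProfile(
        baseline_hr_bpm=72.3,
        phase_hr_bpm={
            "relax1": 73.8, "stress1": 82.9, "relax2": 74.9,
            "stress2": 81.1, "relax3": 73.7,
        },
        attenuation=0.6,
        short_term_amp_s=0.0286,
        overall_amp_s=0.0302,
    )
    rises = []
    for seed in range(20):
        rr = generate_rr_trajectory(prof, schedule, seed)
        b0, d0 = schedule.window("baseline")
        b1, d1 = schedule.window("stress1")
        rises.append(
            mean_hr(window_rr(rr, b1, d1)) - mean_hr(window_rr(rr, b0, d0))
        )
    assert np.mean(rises) == pytest.approx(82.9 - 72.3, abs=1.0)


def test_realized_variability_tracks_profile_amplitudes(schedule):
    prof = AutonomicProfile(
        baseline_hr_bpm=70.0,
        phase_hr_bpm={p: 70.0 for p in PHASES},
        attenuation=1.0,
        short_term_amp_s=0.03,
        overall_amp_s=0.035,
    )
    r_vals, s_vals = [], []
    for seed in range(40):
        rr = generate_rr_trajectory(prof, schedule, seed)
        w = window_rr(rr, *schedule.window("stress1"))
        r_vals.append(rmssd(w))
        s_vals.append(sdnn(w))
    assert np.mean(r_vals) == pytest.approx(0.03, rel=0.15)
    assert np.mean(s_vals) == pytest.approx(0.035, rel=0.15)


def test_synthesize_ecg_peaks_on_beats():
    beats = BeatSeries(np.array([1.0, 2.0, 3.0]))
    wave = synthesize_ecg(beats, 1000.0, duration_s=4.0)
    for t in (1.0, 2.0, 3.0):
        lo = int((t - 0.1) * 1000)
        peak = lo + int(np.argmax(wave.samples[lo : lo + 200]))
        assert abs(peak - t * 1000) <= 1


def test_synthesize_ecg_linearity_and_empty():
    beats = BeatSeries(np.array([0.5, 1.5]))
    w1 = synthesize_ecg(beats, 500.0, EcgTemplate(amplitude_mv=1.0), duration_s=2.0)
    w2 = synthesize_ecg(beats, 500.0, EcgTemplate(amplitude_mv=2.0), duration_s=2.0)
    assert np.allclose(w2.samples, 2.0 * w1.samples)
    empty = synthesize_ecg(BeatSeries(np.empty(0)), 500.0, duration_s=1.0)
    assert not np.any(empty.samples)


def test_synthesize_ecg_rejects_too_close_beats():
    with pytest.raises(ValueError, match="spacing"):
        synthesize_ecg(BeatSeries(np.array([1.0, 1.05])), 1000.0)


def test_contaminate_identity_when_disabled(clean_ecg, default_cfg):
    import dataclasses

    cfg = dataclasses.replace(
        default_cfg,
        emg_snr_db=float("inf"),
        mains_amplitude_mv=0.0,
        drift_amplitude_mv=0.0,
    )
    out = contaminate(clean_ecg, cfg, 0)
    assert np.array_equal(out.samples, clean_ecg.samples)


def test_contaminate_deterministic(clean_ecg, default_cfg):
    a = contaminate(clean_ecg, default_cfg, 5)
    b = contaminate(clean_ecg, default_cfg, 5)
    assert np.array_equal(a.samples, b.samples)


def test_mains_tone_power_parseval():
    """A pure mains sinusoid of amplitude a carries power a^2/2."""
    import dataclasses

    from hrvreact.core import Waveform
    from hrvreact.extract import estimate_spectrum

    cfg = SimulationConfig(
        emg_snr_db=float("inf"),
        mains_amplitude_mv=2.0,
        n_harmonics=0,
        drift_amplitude_mv=0.0,
    )
    silent = Waveform(np.zeros(60_000), 1000.0)
    out = contaminate(silent, cfg, 1)
    spec = estimate_spectrum(out)
    df = spec.frequencies[1] - spec.frequencies[0]
    sel = (spec.frequencies >= 49.0) & (spec.frequencies <= 51.0)
    band_power = float(np.sum(spec.power[sel]) * df)
    assert band_power == pytest.approx(2.0**2 / 2.0, rel=0.10)


def test_generate_subject_ranges_and_control_cluster():
    cfg = SimulationConfig()
    rng = np.random.default_rng(0)
    ctl = generate_subject("control", 2, cfg, rng)
    assert ctl.true_cluster is None
    for seed in range(300):
        s = generate_subject("FM", (seed % 3) + 1, cfg, seed)
        assert 0.0 <= s.pss <= 40.0
        assert 20.0 <= s.stai_a <= 80.0 and 20.0 <= s.stai_b <= 80.0
        assert 0.0 <= s.pcs <= 52.0
        assert 0.0 <= s.fiq_total <= 100.0
        if s.lpa_score is not None:
            assert 3 <= s.lpa_score <= 7
            assert s.physically_active == (s.lpa_score >= 7)


def test_fm_bmi_calibration_monte_carlo():
    cfg = SimulationConfig()
    rng = np.random.default_rng(42)
    bmis = [
        generate_subject("FM", (i % 3) + 1, cfg, rng).bmi for i in range(10_000)
    ]
    assert np.mean(bmis) == pytest.approx(28.2, abs=0.2)


def test_nrs_ratings_deterministic_case_and_bounds():
    import dataclasses

    cfg = SimulationConfig(nrs_stress_effect=0.0, nrs_noise_sd=0.0)
    subj = generate_subject("FM", 1, cfg, 0)
    pain, stress = generate_nrs_ratings(subj, None, cfg, 0)
    assert len(pain) == len(stress) == 6
    assert len(set(stress.tolist())) == 1  # no effect, no noise -> constant
    cfg2 = dataclasses.replace(cfg, nrs_stress_effect=2.0, nrs_noise_sd=0.8)
    for seed in range(100):
        p, s = generate_nrs_ratings(subj, None, cfg2, seed)
        assert p.min() >= 0 and p.max() <= 10
        assert s.min() >= 0 and s.max() <= 10


def test_nrs_stress_effect_monte_carlo(default_cfg):
    diffs = []
    rng = np.random.default_rng(7)
    for i in range(1000):
        subj = generate_subject("FM", (i % 3) + 1, default_cfg, rng)
        _, stress = generate_nrs_ratings(subj, None, default_cfg, rng)
        diffs.append(stress[2] - stress[0])
    assert np.mean(diffs) == pytest.approx(2.0, abs=0.2)


def test_largest_remainder_allocation_exact():
    assert largest_remainder_allocation(51, (9 / 51, 21 / 51, 21 / 51)) == [9, 21, 21]
    assert sum(largest_remainder_allocation(50, (1 / 3, 1 / 3, 1 / 3))) == 50


def test_cohort_counts_and_determinism():
    cfg = SimulationConfig(n_fm=12, n_control=5, master_seed=77)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert len(a.subjects) == 17
    fm_clusters = [s.true_cluster for s in a.subjects if s.group == "FM"]
    assert sorted(set(fm_clusters)) == [1, 2, 3]
    for sid in a.truth_rr:
        assert np.array_equal(a.truth_rr[sid].intervals_s, b.truth_rr[sid].intervals_s)
    sa = [(s.subject_id, s.window, s.hr_bpm) for s in a.truth_summaries]
    sb = [(s.subject_id, s.window, s.hr_bpm) for s in b.truth_summaries]
    assert sa == sb
    # recordings are lazily synthesized but deterministic too
    assert np.array_equal(
        a.recording(a.subjects[0].id).samples,
        b.recording(b.subjects[0].id).samples,
    )


def test_default_cohort_cluster_split(default_cfg):
    counts = largest_remainder_allocation(
        default_cfg.n_fm, default_cfg.cluster_proportions
    )
    assert counts == [9, 21, 21]
    assert default_cfg.n_fm + default_cfg.n_control == 82


def test_recordings_span_protocol(schedule):
    cfg = SimulationConfig(n_fm=1, n_control=1, fs=250.0, master_seed=3)
    cohort = generate_cohort(cfg)
    for s in cohort.subjects:
        wave = cohort.recording(s.id)
        assert wave.duration_s == pytest.approx(1200.0, abs=1e-6)


def test_group_calibration_truth_baselines():
    """Cohort-mean truth baselines sit within 5% of the configured targets."""
    n = 1000
    stats = {}
    for group, cal in (("FM", FM_CALIBRATION), ("control", CONTROL_CALIBRATION)):
        cfg = SimulationConfig(
            n_fm=n if group == "FM" else 0,
            n_control=n if group == "control" else 0,
            master_seed=11,
        )
        cohort = generate_cohort(cfg)
        base = [s for s in cohort.truth_summaries if s.window == "baseline"]
        stats[group] = {
            "rr": np.mean([s.rr_mean_s for s in base]),
            "hr": np.mean([s.hr_bpm for s in base]),
            "rmssd": np.mean([s.rmssd_s for s in base]),
            "sdnn": np.mean([s.sdnn_s for s in base]),
        }
        assert stats[group]["rr"] == pytest.approx(cal.rr_mean_s, rel=0.05)
        assert stats[group]["sdnn"] == pytest.approx(cal.sdnn_s, rel=0.05)
        assert stats[group]["rmssd"] == pytest.approx(
            cal.sdnn_s * cal.rmssd_over_sdnn, rel=0.05
        )
    assert stats["FM"]["hr"] == pytest.approx(72.3, rel=0.05)
    assert stats["control"]["hr"] == pytest.approx(64.5, rel=0.05)


def test_window_mean_instantaneous_hr_dominates_rr_mean(schedule):
    """Jensen: mean of 60/RR >= 60/mean(RR) for every generated window."""
    cfg = SimulationConfig(n_fm=6, n_control=4, master_seed=2)
    cohort = generate_cohort(cfg)
    for s in cohort.truth_summaries:
        if s.hr_bpm is not None:
            assert s.hr_bpm >= 60.0 / s.rr_mean_s - 1e-9
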