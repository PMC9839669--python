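"""Synthetic stress-protocol cohort generator.

Simulates a cohort of fibromyalgia (FM) patients and healthy controls
undergoing the 20-min alternating relaxation / cognitive-stress protocol,
with known ground truth at every level:

* a beat-time (RR tachogram) model per subject: phase-piecewise mean RR
  with 10-s linear ramps, one sinusoidal respiratory component, and AR(1)
  beat-to-beat noise, calibrated so the realized short-term (RMSSD) and
  total (SDNN) variability match per-subject target amplitudes;
* an ECG waveform (Ricker/"Mexican-hat" QRS template on each beat),
  contaminated to the surface-EMG recording condition: EMG-band Gaussian
  noise at a configurable QRS-band SNR, mains interference at 50 Hz and
  harmonics, and slow baseline drift;
* per-subject covariates and questionnaire scores (FIQ, PCS, PSS,
  STAI-A/B) with group- and cluster-graded structure, and numeric rating
  scale (NRS) pain/stress ratings at the six protocol timepoints.

Group-level calibration targets are the published descriptive statistics
of the study population (e.g. FM baseline HR 72.3 bpm, RRmean 0.844 s);
the FM-vs-control stress-reactivity truth is encoded as additive
group-by-phase interaction terms (relax1 reference) whose defaults equal
the published adjusted model coefficients, with cluster deviations that
are proportion-weighted to mean zero so the group-level truth is exact
under any cluster mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import BeatSeries, RRSeries, Waveform
from .metrics import phase_summaries
from .schedule import (
    PHASE_LABELS,
    STRESS_PHASES,
    PhaseSchedule,
    build_default_schedule,
)

# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class GroupCalibration:
    """Descriptive targets for one study group (baseline window)."""

    rr_mean_s: float
    rr_sd_s: float
    sdnn_s: float
    sdnn_cv: float  # coefficient of variation across subjects
    rmssd_over_sdnn: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    p_smoker: float
    p_active: float
    # HR change of each phase level from the baseline level, bpm
    phase_deltas_bpm: dict[str, float] = field(default_factory=dict)


FM_CALIBRATION = GroupCalibration(
    rr_mean_s=0.844,
    rr_sd_s=0.134,
    sdnn_s=0.0302,
    sdnn_cv=0.0196 / 0.0302,
    rmssd_over_sdnn=0.0286 / 0.0302,
    age_mean=45.1,
    age_sd=12.7,
    bmi_mean=28.2,
    bmi_sd=5.87,
    p_smoker=12 / 51,
    p_active=20 / 51,
)

CONTROL_CALIBRATION = GroupCalibration(
    rr_mean_s=0.934,
    rr_sd_s=0.118,
    sdnn_s=0.0373,
    sdnn_cv=0.0211 / 0.0373,
    rmssd_over_sdnn=0.0363 / 0.0373,
    age_mean=46.0,
    age_sd=11.7,
    bmi_mean=24.7,
    bmi_sd=3.27,
    p_smoker=2 / 31,
    p_active=16 / 31,
    # control phase-level HR deltas from the baseline level (study group
    # means: 65.9, 77.5, 68.4, 77.7, 66.5 minus baseline 64.5)
    phase_deltas_bpm={
        "relax1": 1.4,
        "stress1": 13.0,
        "relax2": 3.9,
        "stress2": 13.2,
        "relax3": 2.0,
    },
)

#: FM-vs-control phase interactions (relax1 reference), bpm; defaults are
#: the published covariate-adjusted model coefficients.
DEFAULT_GROUP_INTERACTIONS_BPM = {
    "stress1": -2.41,
    "relax2": -1.34,
    "stress2": -4.41,
    "relax3": -0.79,
}


@dataclass(frozen=True)
class ClusterEffects:
    """Cluster-graded structure of the FM group.

    All per-cluster vectors are re-centred at generation time with the
    actual cluster proportions (additive terms to weighted mean zero,
    multiplicative scales to weighted mean one), so group-level
    calibration is unaffected by the cluster mix.
    """

    # baseline RRmean offsets, s (cluster 1 = slowest heart rate)
    rr_offset_s: tuple[float, float, float] = (0.08, 0.01, -0.0443)
    # multiplicative scale on SDNN/RMSSD targets (cluster 1 = highest HRV)
    hrv_scale: tuple[float, float, float] = (1.30, 0.95, 0.921)
    # raw per-cluster FM-vs-control interactions at the stress phases, bpm;
    # cluster 1 responds like controls, cluster 3 is most attenuated
    stress1_interaction_bpm: tuple[float, float, float] = (0.0, -2.2, -3.65)
    stress2_interaction_bpm: tuple[float, float, float] = (0.0, -4.0, -6.71)
    # questionnaire locations, (cluster1, cluster2, cluster3)
    fiq_total: tuple[float, float, float] = (45.0, 60.0, 68.0)
    fiq_anxiety: tuple[float, float, float] = (2.5, 6.5, 7.0)
    fiq_depression: tuple[float, float, float] = (2.0, 4.5, 6.5)
    pcs: tuple[float, float, float] = (15.0, 22.0, 28.0)
    pss: tuple[float, float, float] = (12.0, 20.0, 24.0)
    stai: tuple[float, float, float] = (30.0, 42.0, 48.0)
    nrs_pain_level: tuple[float, float, float] = (3.0, 5.5, 6.0)
    nrs_stress_level: tuple[float, float, float] = (2.0, 4.0, 5.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    The arithmetic-stressor constants (number series, false feedbacks,
    masking-noise level) are protocol provenance recorded in the output
    manifest; no auditory stimulus is simulated.
    """

    n_fm: int = 51
    n_control: int = 31
    cluster_proportions: tuple[float, ...] = (9 / 51, 21 / 51, 21 / 51)
    fs: float = 1000.0
    mains_hz: float = 50.0
    n_harmonics: int = 2
    mains_amplitude_mv: float = 2.0
    harmonic_decay: float = 0.5
    emg_snr_db: float = 0.0
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    drift_amplitude_mv: float = 0.5
    drift_period_s: float = 30.0
    ramp_s: float = 10.0
    phase_hr_noise_bpm: float = 2.0
    resp_freq_range_hz: tuple[float, float] = (0.2, 0.3)
    nrs_stress_effect: float = 2.0
    nrs_pain_stress_effect: float = 0.0
    nrs_noise_sd: float = 0.8
    covariate_missing_prob: float = 5 / 82
    fiq_item_34_missing_prob: float = 0.4
    group_interactions_bpm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_INTERACTIONS_BPM)
    )
    cluster_effects: ClusterEffects = field(default_factory=ClusterEffects)
    # arithmetic stressor metadata
    stressor_n_series: int = 14
    stressor_digits_per_series: int = 10
    stressor_digit_range: tuple[int, int] = (0, 9)
    stressor_false_feedbacks: int = 4
    masking_noise_db: float = 60.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fm < 0 or self.n_control < 0 or self.n_fm + self.n_control < 1:
            raise ValueError("cohort must contain at least one subject")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if self.fs < 250:
            raise ValueError("sampling rate must be at least 250 Hz")


@dataclass(frozen=True)
class AutonomicProfile:
    """Per-subject autonomic ground truth driving the RR tachogram."""

    baseline_hr_bpm: float
    phase_hr_bpm: dict[str, float]
    attenuation: float  # stress2 rise relative to the control rise, in [0, 1]
    short_term_amp_s: float  # drives RMSSD
    overall_amp_s: float  # drives SDNN
    resp_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        for hr in (self.baseline_hr_bpm, *self.phase_hr_bpm.values()):
            if not 40.0 <= hr <= 180.0:
                raise ValueError(f"mean HR {hr:.1f} outside [40, 180] bpm")
        if self.short_term_amp_s < 0 or self.overall_amp_s < 0:
            raise ValueError("variability amplitudes must be non-negative")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation factor must lie in [0, 1]")


@dataclass
class Subject:
    id: str
    group: str  # "FM" or "control"
    true_cluster: int | None
    age: float
    bmi: float
    smoker: bool
    lpa_score: int | None
    physically_active: bool | None
    fiq_items: dict[int, float | None]
    fiq_total: float | None
    pcs: float | None
    pss: float
    stai_a: float
    stai_b: float
    nrs_pain: np.ndarray | None = None
    nrs_stress: np.ndarray | None = None


# --------------------------------------------------------------------------
# Helpers


def _centred_offsets(raw: tuple[float, ...], w: np.ndarray) -> np.ndarray:
    v = np.asarray(raw, dtype=float)
    return v - float(w @ v)


def _centred_scales(raw: tuple[float, ...], w: np.ndarray) -> np.ndarray:
    v = np.asarray(raw, dtype=float)
    return v / float(w @ v)


def largest_remainder_allocation(n: int, proportions) -> list[int]:
    """Deterministic integer allocation of n items to proportions."""
    p = np.asarray(proportions, dtype=float)
    quotas = n * p
    counts = np.floor(quotas).astype(int)
    short = n - int(counts.sum())
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sig2 = math.log1p(cv * cv)
    mu = math.log(mean) - sig2 / 2.0
    return mu, math.sqrt(sig2)


def _ar1_var_bias(phi: float, n: int) -> float:
    """E[sample variance] / sigma^2 for an AR(1) over an n-point window."""
    if n < 2 or phi <= 0:
        return 1.0
    k = np.arange(1, n)
    s = float(np.sum((n - k) * phi**k))
    return max(1.0 - 2.0 * s / (n * (n - 1)), 0.05)


def calibrate_rr_noise(
    short_amp_s: float,
    overall_amp_s: float,
    resp_freq_hz: float,
    rr_mean_s: float,
    window_s: float = 30.0,
    resp_share: float = 0.5,
) -> tuple[float, float, float]:
    """Solve (respiratory amplitude, AR(1) sd, AR(1) phi) for the targets.

    The realized window metrics decompose as

        SDNN^2  ~= s^2/2 + c(phi, n) * sigma^2
        RMSSD^2 ~= 2 s^2 sin^2(pi f T) + 2 sigma^2 (1 - phi)

    where s is the respiratory sinusoid amplitude, T the mean beat
    interval, and c the finite-window variance bias of an AR(1).
    ``resp_share`` sets the fraction of RMSSD^2 supplied by respiration.
    """
    R2, S2 = short_amp_s**2, overall_amp_s**2
    if S2 == 0.0 and R2 == 0.0:
        return 0.0, 0.0, 0.0
    if S2 == 0.0:
        raise ValueError("short-term amplitude requires non-zero total amplitude")
    sin2 = math.sin(math.pi * resp_freq_hz * rr_mean_s) ** 2
    s2 = min(resp_share * R2 / max(2.0 * sin2, 1e-9), 1.5 * S2)
    resp_diff_term = 2.0 * s2 * sin2
    n = max(int(round(window_s / rr_mean_s)), 4)
    c, phi, sigma2 = 1.0, 0.0, max(S2 - s2 / 2.0, 1e-14)
    for _ in range(6):
        sigma2 = max((S2 - s2 / 2.0) / c, 1e-14)
        phi = 1.0 - max(R2 - resp_diff_term, 0.0) / (2.0 * sigma2)
        phi = min(max(phi, 0.0), 0.97)
        c = _ar1_var_bias(phi, n)
    return math.sqrt(s2), math.sqrt(sigma2), phi


# --------------------------------------------------------------------------
# RR trajectory and ECG synthesis


def _hr_level_nodes(
    profile: AutonomicProfile, schedule: PhaseSchedule, ramp_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear HR level (bpm) vs time, with ramped transitions."""
    base_end = schedule.windows.get("baseline", (0.0, 30.0))
    t_nodes = [schedule.start_s]
    h_nodes = [profile.baseline_hr_bpm]
    prev_hr = profile.baseline_hr_bpm
    boundaries = [(base_end[0] + base_end[1], schedule.phases[0].label)]
    boundaries += [(p.start_s, p.label) for p in schedule.phases[1:]]
    for t0, label in boundaries:
        hr = profile.phase_hr_bpm[label]
        t_nodes += [t0, min(t0 + ramp_s, schedule.end_s)]
        h_nodes += [prev_hr, hr]
        prev_hr = hr
    t_nodes.append(schedule.end_s)
    h_nodes.append(prev_hr)
    return np.asarray(t_nodes), np.asarray(h_nodes)


def generate_rr_trajectory(
    profile: AutonomicProfile,
    schedule: PhaseSchedule | None = None,
    rng_seed: int | np.random.Generator = 0,
    ramp_s: float = 10.0,
    rr_floor_s: float = 0.3,
) -> RRSeries:
    """Simulate beat times over the protocol and return the RR series.

    Instantaneous RR = phase-interpolated mean RR + respiratory sinusoid
    + AR(1) noise; the first beat falls at the recording start.
    """
    if schedule is None:
        schedule = build_default_schedule()
    if profile.baseline_hr_bpm <= 0:
        raise ValueError("degenerate profile: non-positive mean HR")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    t_nodes, h_nodes = _hr_level_nodes(profile, schedule, ramp_s)
    s_amp, sigma, phi = calibrate_rr_noise(
        profile.short_term_amp_s,
        profile.overall_amp_s,
        profile.resp_freq_hz,
        60.0 / profile.baseline_hr_bpm,
    )
    innov_sd = sigma * math.sqrt(max(1.0 - phi * phi, 0.0))
    omega = 2.0 * math.pi * profile.resp_freq_hz
    resp_phase = float(rng.uniform(0.0, 2.0 * math.pi)) if s_amp else 0.0
    e = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    # pre-draw innovations generously (mean RR >= rr_floor bounds the count)
    end = schedule.end_s
    max_beats = int(end / rr_floor_s) + 2
    z = rng.standard_normal(max_beats) if innov_sd > 0 else None

    tn, hn = t_nodes.tolist(), h_nodes.tolist()
    interp = np.interp
    times = [schedule.start_s]
    t = schedule.start_s
    k = 0
    while True:
        hr = float(interp(t, tn, hn))
        rr = 60.0 / hr
        if s_amp:
            rr += s_amp * math.sin(omega * t + resp_phase)
        rr += e
        rr = max(rr, rr_floor_s)
        t += rr
        if t > end:
            break
        times.append(t)
        if z is not None:
            e = phi * e + innov_sd * float(z[k])
            k += 1
    beats = np.asarray(times)
    if beats.size < 2:
        return RRSeries.empty()
    return RRSeries(np.diff(beats), beats[1:])


def beat_times_from_rr(rr: RRSeries) -> np.ndarray:
    """Recover the beat-time vector (including the opening beat)."""
    if rr.n == 0:
        return np.empty(0)
    t0 = rr.interval_end_times_s[0] - rr.intervals_s[0]
    return np.concatenate([[t0], rr.interval_end_times_s])


@dataclass(frozen=True)
class EcgTemplate:
    """Ricker-wavelet QRS template (positive peak at the beat time)."""

    width_s: float = 0.08
    amplitude_mv: float = 1.0
    t_wave_amp_mv: float = 0.0  # optional low-frequency T wave
    t_wave_offset_s: float = 0.25
    t_wave_width_s: float = 0.16


def _ricker(t: np.ndarray, width_s: float) -> np.ndarray:
    sig = width_s / 6.0
    x = (t / sig) ** 2
    return (1.0 - x) * np.exp(-x / 2.0)


def synthesize_ecg(
    rr: RRSeries | BeatSeries,
    fs: float,
    template: EcgTemplate | None = None,
    duration_s: float | None = None,
    channel_label: str = "EMG-ECG-MIX",
) -> Waveform:
    """Render an ECG-like waveform with one QRS deflection per beat."""
    if fs < 250:
        raise ValueError("sampling rate must be at least 250 Hz")
    template = template or EcgTemplate()
    beats = (
        rr.beat_times_s if isinstance(rr, BeatSeries) else beat_times_from_rr(rr)
    )
    if beats.size >= 2 and np.min(np.diff(beats)) < template.width_s:
        raise ValueError("beat spacing shorter than the QRS template width")
    if duration_s is None:
        duration_s = float(beats[-1]) + 2 * template.width_s if beats.size else 1.0
    n = int(round(duration_s * fs))
    samples = np.zeros(n)
    half = 3.0 * template.width_s
    for tb in beats:
        i0 = max(int(math.ceil((tb - half) * fs)), 0)
        i1 = min(int(math.floor((tb + half) * fs)) + 1, n)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / fs - tb
        samples[i0:i1] += template.amplitude_mv * _ricker(tt, template.width_s)
        if template.t_wave_amp_mv:
            tc = tt - template.t_wave_offset_s
            sig = template.t_wave_width_s / 2.0
            samples[i0:i1] += template.t_wave_amp_mv * np.exp(
                -(tc**2) / (2 * sig**2)
            )
    return Waveform(samples, fs, channel_label=channel_label)


def _band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return float(np.mean(y * y))


def contaminate(
    wave: Waveform,
    cfg: SimulationConfig,
    rng_seed: int | np.random.Generator = 0,
) -> Waveform:
    """Degrade a clean ECG to the surface-EMG recording condition.

    Adds band-limited EMG noise scaled to ``cfg.emg_snr_db`` measured on
    the 10-40 Hz QRS band, mains sinusoids at the line frequency and its
    harmonics, and slow sinusoidal baseline drift.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    x = wave.samples.copy()
    t = wave.times_s
    nyq = wave.fs / 2.0
    if np.isfinite(cfg.emg_snr_db):
        lo = cfg.emg_band_hz[0]
        hi = min(cfg.emg_band_hz[1], 0.9 * nyq)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=wave.fs, output="sos")
        noise = sps.sosfiltfilt(sos, rng.standard_normal(x.size))
        sig_p = _band_power(wave.samples, wave.fs, 10.0, 40.0)
        noise_p = _band_power(noise, wave.fs, 10.0, 40.0)
        if sig_p > 0 and noise_p > 0:
            noise *= math.sqrt(
                sig_p / (noise_p * 10.0 ** (cfg.emg_snr_db / 10.0))
            )
        x = x + noise
    if cfg.mains_amplitude_mv > 0:
        for h in range(cfg.n_harmonics + 1):
            f = cfg.mains_hz * (h + 1)
            if f >= nyq:
                break
            amp = cfg.mains_amplitude_mv * cfg.harmonic_decay**h
            x = x + amp * np.sin(
                2 * math.pi * f * t + float(rng.uniform(0, 2 * math.pi))
            )
    if cfg.drift_amplitude_mv > 0:
        x = x + cfg.drift_amplitude_mv * np.sin(
            2 * math.pi * t / cfg.drift_period_s
            + float(rng.uniform(0, 2 * math.pi))
        )
    return wave.copy_with(x)


# --------------------------------------------------------------------------
# Subjects, profiles, ratings


def _group_cal(group: str) -> GroupCalibration:
    if group == "FM":
        return FM_CALIBRATION
    if group == "control":
        return CONTROL_CALIBRATION
    raise ValueError(f"unknown group {group!r}")


def build_profile(
    group: str,
    true_cluster: int | None,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> AutonomicProfile:
    """Draw a subject's autonomic ground-truth profile."""
    cal = _group_cal(group)
    w = np.asarray(cfg.cluster_proportions)
    eff = cfg.cluster_effects
    rr_off = _centred_offsets(eff.rr_offset_s, w)
    hrv_sc = _centred_scales(eff.hrv_scale, w)
    dev1 = _centred_offsets(eff.stress1_interaction_bpm, w)
    dev2 = _centred_offsets(eff.stress2_interaction_bpm, w)

    ci = (true_cluster - 1) if (group == "FM" and true_cluster) else None
    mu_rr = cal.rr_mean_s + (rr_off[ci] if ci is not None else 0.0)
    r0 = float(np.clip(rng.normal(mu_rr, cal.rr_sd_s), 0.45, 1.35))
    hr0 = 60.0 / r0

    deltas = CONTROL_CALIBRATION.phase_deltas_bpm
    inter = dict.fromkeys(PHASE_LABELS, 0.0)
    if group == "FM":
        for ph, v in cfg.group_interactions_bpm.items():
            inter[ph] = v
        if ci is not None:
            inter["stress1"] += float(dev1[ci])
            inter["stress2"] += float(dev2[ci])
    phase_hr = {}
    for ph in PHASE_LABELS:
        noise = rng.normal(0.0, cfg.phase_hr_noise_bpm)
        phase_hr[ph] = float(
            np.clip(hr0 + deltas[ph] + inter[ph] + noise, 40.0, 180.0)
        )
    control_rise = deltas["stress2"] - deltas["relax1"]
    rise = phase_hr["stress2"] - phase_hr["relax1"]
    attenuation = float(np.clip(rise / control_rise, 0.0, 1.0))

    scale = float(hrv_sc[ci]) if ci is not None else 1.0
    mu, sig = _lognormal_params(cal.sdnn_s * scale, cal.sdnn_cv)
    sdnn_amp = float(rng.lognormal(mu, sig))
    ratio = float(np.clip(rng.normal(cal.rmssd_over_sdnn, 0.08), 0.3, 1.2))
    rmssd_amp = sdnn_amp * ratio
    resp_f = float(rng.uniform(*cfg.resp_freq_range_hz))
    return AutonomicProfile(
        baseline_hr_bpm=float(np.clip(hr0, 40.0, 180.0)),
        phase_hr_bpm=phase_hr,
        attenuation=attenuation,
        short_term_amp_s=rmssd_amp,
        overall_amp_s=sdnn_amp,
        resp_freq_hz=resp_f,
    )


def _clip_round(x: float, lo: float, hi: float) -> float:
    return float(np.clip(np.rint(x), lo, hi))


def generate_subject(
    group: str,
    true_cluster: int | None,
    cfg: SimulationConfig,
    rng_seed: int | np.random.Generator = 0,
    subject_id: str = "S01",
) -> Subject:
    """Draw covariates and questionnaire scores for one subject.

    Controls carry no cluster label; FM questionnaire locations are
    cluster-graded (cluster 3 > cluster 2 > cluster 1 for anxiety and
    depression).  All scores are clipped to their instrument ranges.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cal = _group_cal(group)
    if group != "FM":
        true_cluster = None
    eff = cfg.cluster_effects
    ci = (true_cluster - 1) if true_cluster else None

    age = float(np.clip(rng.normal(cal.age_mean, cal.age_sd), 18.0, 65.0))
    bmi = float(np.clip(rng.normal(cal.bmi_mean, cal.bmi_sd), 15.0, 60.0))
    smoker = bool(rng.random() < cal.p_smoker)
    if rng.random() < cfg.covariate_missing_prob:
        lpa: int | None = None
        active: bool | None = None
    else:
        if rng.random() < cal.p_active:
            lpa = 7
        else:
            lpa = int(rng.integers(3, 7))  # 3..6
        active = lpa >= 7

    def loc(values: tuple[float, float, float], control: float) -> float:
        return values[ci] if ci is not None else control

    fiq_items: dict[int, float | None] = {}
    if group == "FM":
        anx = loc(eff.fiq_anxiety, 0.0)
        dep = loc(eff.fiq_depression, 0.0)
        fiq_items[1] = _clip_round(rng.normal(1.6, 0.7), 0, 3)
        fiq_items[2] = _clip_round(rng.normal(4.0, 1.8), 0, 7)
        for item in (3, 4):
            fiq_items[item] = (
                None
                if rng.random() < cfg.fiq_item_34_missing_prob
                else _clip_round(rng.normal(3.0, 2.0), 0, 10)
            )
        for item, mu_i in ((5, 6.0), (6, 7.0), (7, 6.5), (8, 6.0)):
            fiq_items[item] = _clip_round(rng.normal(mu_i, 2.0), 0, 10)
        fiq_items[9] = _clip_round(rng.normal(anx, 2.0), 0, 10)
        fiq_items[10] = _clip_round(rng.normal(dep, 2.0), 0, 10)
        fiq_total = float(
            np.clip(rng.normal(loc(eff.fiq_total, 0.0), 12.0), 0.0, 100.0)
        )
        pcs = float(np.clip(rng.normal(loc(eff.pcs, 0.0), 8.0), 0.0, 52.0))
    else:
        fiq_total = None
        pcs = None
    pss = float(np.clip(rng.normal(loc(eff.pss, 11.0), 6.0), 0.0, 40.0))
    stai_mu = loc(eff.stai, 30.0)
    stai_a = float(np.clip(rng.normal(stai_mu, 8.0), 20.0, 80.0))
    stai_b = float(np.clip(rng.normal(stai_mu, 8.0), 20.0, 80.0))

    return Subject(
        id=subject_id,
        group=group,
        true_cluster=true_cluster,
        age=age,
        bmi=bmi,
        smoker=smoker,
        lpa_score=lpa,
        physically_active=active,
        fiq_items=fiq_items,
        fiq_total=fiq_total,
        pcs=pcs,
        pss=pss,
        stai_a=stai_a,
        stai_b=stai_b,
    )


#: rating timepoints: start, then after each of the five phases
NRS_TIMEPOINTS = ("start", "post_relax1", "post_stress1", "post_relax2",
                  "post_stress2", "post_relax3")
#: indices of the ratings taken immediately after a stress phase
NRS_POST_STRESS_IDX = (2, 4)


def generate_nrs_ratings(
    subject: Subject,
    profile: AutonomicProfile | None,
    cfg: SimulationConfig,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Six-point NRS pain and stress series (0-10 integers).

    Stress ratings rise by ``cfg.nrs_stress_effect`` at the readings that
    follow a stress phase; pain is level-graded by cluster but, by
    default, carries no phase effect.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    eff = cfg.cluster_effects
    ci = (subject.true_cluster - 1) if subject.true_cluster else None
    pain_level = eff.nrs_pain_level[ci] if ci is not None else (
        4.5 if subject.group == "FM" else 0.5
    )
    stress_level = eff.nrs_stress_level[ci] if ci is not None else (
        3.0 if subject.group == "FM" else 2.0
    )
    n = len(NRS_TIMEPOINTS)
    pain = np.full(n, pain_level)
    stress = np.full(n, stress_level)
    for i in NRS_POST_STRESS_IDX:
        stress[i] += cfg.nrs_stress_effect
        pain[i] += cfg.nrs_pain_stress_effect
    if cfg.nrs_noise_sd > 0:
        pain = pain + rng.normal(0.0, cfg.nrs_noise_sd, n)
        stress = stress + rng.normal(0.0, cfg.nrs_noise_sd, n)
    pain = np.clip(np.rint(pain), 0, 10).astype(int)
    stress = np.clip(np.rint(stress), 0, 10).astype(int)
    return pain, stress


# --------------------------------------------------------------------------
# Cohort


@dataclass
class Cohort:
    """A generated cohort with per-subject ground truth.

    Recordings are synthesized lazily (deterministically per subject)
    via :meth:`recording` to keep memory bounded; ``generate_cohort``
    can attach them eagerly for small cohorts.
    """

    config: SimulationConfig
    schedule: PhaseSchedule
    subjects: list[Subject]
    profiles: dict[str, AutonomicProfile]
    truth_rr: dict[str, RRSeries]
    truth_summaries: list  # HRVSummary
    recordings: dict[str, Waveform] = field(default_factory=dict)
    _record_seeds: dict[str, np.random.SeedSequence] = field(
        default_factory=dict, repr=False
    )

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def recording(self, subject_id: str) -> Waveform:
        """Contaminated waveform for one subject (synthesized on demand)."""
        if subject_id in self.recordings:
            return self.recordings[subject_id]
        cfg = self.config
        clean = synthesize_ecg(
            self.truth_rr[subject_id],
            cfg.fs,
            duration_s=self.schedule.total_duration_s,
        )
        rng = np.random.default_rng(self._record_seeds[subject_id])
        return contaminate(clean, cfg, rng)


def generate_cohort(
    cfg: SimulationConfig,
    schedule: PhaseSchedule | None = None,
    include_recordings: bool = False,
) -> Cohort:
    """Generate the full cohort: subjects, truth RR, truth HRV summaries.

    Cluster allocation of the FM group is deterministic (largest
    remainder on the configured proportions), so the default run yields
    the 9/21/21 split exactly.  All randomness derives from
    ``cfg.master_seed`` through spawned seed sequences, one per subject.
    """
    if schedule is None:
        schedule = build_default_schedule()
    n_total = cfg.n_fm + cfg.n_control
    root = np.random.SeedSequence(cfg.master_seed)
    children = root.spawn(n_total)

    counts = largest_remainder_allocation(cfg.n_fm, cfg.cluster_proportions)
    clusters: list[int | None] = []
    for c, k in enumerate(counts, start=1):
        clusters += [c] * k

    subjects: list[Subject] = []
    profiles: dict[str, AutonomicProfile] = {}
    truth_rr: dict[str, RRSeries] = {}
    summaries: list = []
    recordings: dict[str, Waveform] = {}
    record_seeds: dict[str, np.random.SeedSequence] = {}

    specs = [("FM", clusters[i], f"FM{i + 1:02d}") for i in range(cfg.n_fm)]
    specs += [
        ("control", None, f"C{i + 1:02d}") for i in range(cfg.n_control)
    ]
    for (group, cluster, sid), child in zip(specs, children):
        ss_subj, ss_prof, ss_rr, ss_nrs, ss_noise = child.spawn(5)
        subj = generate_subject(
            group, cluster, cfg, np.random.default_rng(ss_subj), subject_id=sid
        )
        prof = build_profile(group, cluster, cfg, np.random.default_rng(ss_prof))
        rr = generate_rr_trajectory(
            prof, schedule, np.random.default_rng(ss_rr), ramp_s=cfg.ramp_s
        )
        subj.nrs_pain, subj.nrs_stress = generate_nrs_ratings(
            subj, prof, cfg, np.random.default_rng(ss_nrs)
        )
        subjects.append(subj)
        profiles[sid] = prof
        truth_rr[sid] = rr
        summaries.extend(phase_summaries(rr, schedule, sid))
        record_seeds[sid] = ss_noise

    cohort = Cohort(
        config=cfg,
        schedule=schedule,
        subjects=subjects,
        profiles=profiles,
        truth_rr=truth_rr,
        truth_summaries=summaries,
        recordings=recordings,
        _record_seeds=record_seeds,
    )
    if include_recordings:
        for s in subjects:
            cohort.recordings[s.id] = cohort.recording(s.id)
    return cohort


def implied_group_interaction(cfg: SimulationConfig, phase: str) -> float:
    """Ground-truth FM-vs-control interaction (bpm) at a phase.

    Cluster deviations are proportion-centred, so this equals the
    configured group interaction exactly; exposed for recovery checks.
    """
    return float(cfg.group_interactions_bpm.get(phase, 0.0))
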