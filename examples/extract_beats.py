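"""Recover beat times from one EMG-contaminated recording.

Synthesizes a clean ECG from a known tachogram, degrades it with
EMG-band noise at 0 dB QRS-band SNR plus 50-Hz mains and drift, runs
the full extraction chain, and scores the detected beats against the
generator truth.
"""

import numpy as np

from hrvreact.extract import beat_detection_scores, extract_rr
from hrvreact.schedule import build_default_schedule
from hrvreact.simulate import (
    SimulationConfig,
    beat_times_from_rr,
    build_profile,
    contaminate,
    generate_rr_trajectory,
    synthesize_ecg,
)

schedule = build_default_schedule()
cfg = SimulationConfig()
profile = build_profile("FM", 2, cfg, np.random.default_rng(7))
rr_true = generate_rr_trajectory(profile, schedule, 7)

clean = synthesize_ecg(rr_true, cfg.fs, duration_s=schedule.total_duration_s)
dirty = contaminate(clean, cfg, 7)
rr_est, info = extract_rr(dirty)

scores = beat_detection_scores(
    beat_times_from_rr(rr_true), beat_times_from_rr(rr_est)
)
print(f"flattened mains bands: {info['bands_flattened']}")
print(f"beats: {scores['n_truth']} true, {scores['n_est']} detected")
print(f"sensitivity {100 * scores['sensitivity']:.2f} %, "
      f"PPV {100 * scores['ppv']:.2f} %")
print(f"median RR error {1000 * scores['median_rr_err_s']:.2f} ms")
# At the default noise level both rates should exceed 99% and the RR
# error should stay near 1 ms -- accurate enough for RMSSD/SDNN work.
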