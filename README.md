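# hrvreact

Heart-rate-variability (HRV) stress-reactivity analysis for protocols of
alternating relaxation and cognitive stress, built around the study
design used in fibromyalgia (FM) research: patients and matched controls
follow a 20-minute protocol of five 4-minute phases (relax, mental
arithmetic, relax, arithmetic, relax) while a single-channel recording —
surface EMG with an embedded ECG component — is acquired.  The package
is for researchers who need the full chain reproducible in Python:

1. **ECG recovery from sEMG-grade signals** — detrend, automatic
   detection and spectral flattening of mains-interference peaks
   (50 Hz and harmonics), 3rd-order Butterworth bandpass to 10–40 Hz,
   single-channel PCA via time-delay embedding, energy-based QRS
   detection with a rhythm-consistency pass, and RR artifact rejection.
2. **Time-domain HRV** over protocol windows (30-s baseline; 3-min
   sample per phase starting at +20 s): HR, RRmean, RMSSD, SDNN.
3. **Reactivity modelling** by feasible generalized least squares with
   exchangeable within-subject correlation:
   `outcome = group × time + baseline (+ BMI + smoking + activity)`.
4. **Patient stratification** by constrained k-means on z-scored
   reactivity (ΔHR, ΔRRmean = stress2 − baseline) under the sample-size
   rule n ≥ 10·d·k, with minimum within-cluster-sum-of-squares model
   selection and cluster characterisation (ANOVA + Tukey HSD, sparse
   cluster × time GLS).
5. **A synthetic cohort generator** with ground truth at every level —
   phase-structured RR tachograms (piecewise mean RR + respiratory
   sinusoid + AR(1) noise), ECG waveforms, EMG/mains/drift
   contamination, covariates, questionnaires and subjective ratings —
   calibrated to published group statistics (FM baseline HR
   72.3 bpm, RRmean 0.844 s vs control 64.5 bpm, 0.934 s; stress2 HR
   interaction −4.41 bpm).

The central model, for each HRV outcome with relax1 as the time
reference, is

    y_it = β0 + β_b · baseline_i + γ · FM_i + Σ_t τ_t + Σ_t δ_t · FM_i + ε_it ,
    Corr(ε_it, ε_is) = ρ  (exchangeable within subject),

estimated by iterated feasible GLS; the δ_t (group × time interactions)
measure how much the patients' stress response differs from the
controls'.

## Worked example

```
python examples/fit_reactivity_model.py
```

simulates a default cohort (51 FM + 31 controls), builds the long table
from generator-truth HRV, and fits the heart-rate model:

```
long table: 410 rows (82 subjects x 5 phases)
exchangeable rho = 0.181; n = 410

term                          estimate               95% CI        p
(Intercept)                       3.61         [1.24, 5.97]  0.00289
baseline                          0.97         [0.94, 1.00] 1.97e-193
group[FM]                         0.39        [-0.79, 1.57]    0.514
time[stress1]                    11.74       [10.58, 12.90] 9.64e-62
time[relax2]                      3.20         [2.04, 4.36] 9.89e-08
time[stress2]                    12.26       [11.10, 13.42] 1.34e-65
group[FM]:time[stress1]          -2.67       [-4.14, -1.20]  0.00039
group[FM]:time[stress2]          -4.69       [-6.16, -3.22] 8.96e-10
...
```

Reading it: both stressors raise control heart rate by ~12 bpm over
relax1; the negative FM interactions say the patients' rise is smaller,
most clearly at the repeated stressor (here −4.69 bpm against a
generator truth of −4.41 — one cohort is one random draw).  The baseline
coefficient near 1 shows within-subject tracking of resting heart rate.

`examples/extract_beats.py` runs the signal-level chain on one
contaminated 20-minute recording (EMG noise at 0 dB QRS-band SNR,
50/100/150 Hz mains, drift):

```
flattened mains bands: [(49.5, 50.5), (99.5, 100.5), (149.5, 150.5)]
beats: 1492 true, 1490 detected
sensitivity 99.53 %, PPV 99.66 %
median RR error 1.41 ms
```

i.e. fewer than one beat in a hundred is missed or spurious, and beat
timing is accurate to about a millisecond — sufficient for RMSSD/SDNN.
`examples/simulate_cohort.py` and `examples/cluster_patients.py` cover
cohort generation and the stratification step the same way.

A thin CLI wraps the same stages
(`hrvreact simulate|extract|hrv|model|cluster|report|all`); `hrvreact
all --out run/ --seed 7` writes subject tables, HRV summaries, model
coefficient tables, cluster assignments, a plain-text report and a
manifest with SHA-256 digests of every output.  Two runs from the same
seed are byte-identical.

## Layout

```
src/hrvreact/
  schedule.py   protocol phases and analysis windows
  core.py       Waveform / BeatSeries / RRSeries / HRVSummary containers
  simulate.py   synthetic cohort generator (tachograms, ECG, subjects)
  extract.py    ECG/RR recovery chain
  metrics.py    time-domain HRV and reactivity
  models.py     feasible GLS, group tests, ANOVA + Tukey
  cluster.py    constrained k-means stratification and characterisation
  io.py         delimited-text and EDF signal/table I/O
  pipeline.py   end-to-end driver, report, run manifest
  cli.py        thin click CLI
docs/methods.md model documentation and design notes
examples/       one narrative script per capability
tests/          pytest suite (unit, property, acceptance)
```
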