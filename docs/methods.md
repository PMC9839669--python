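# Methods

`hrvreact` implements, end to end, an analysis of heart-rate-variability
(HRV) responses to alternating relaxation and cognitive stress in
fibromyalgia (FM) patients and healthy controls: recovery of ECG beat
times from surface-EMG-grade recordings, time-domain HRV summarisation
over protocol windows, baseline-adjusted generalized-least-squares (GLS)
reactivity modelling, and constrained k-means stratification of patients
by stress reactivity.  Because clinical recordings of this kind are not
generally shareable, the package carries a first-class synthetic cohort
generator with known ground truth at every stage; this note documents the
models, their assumptions, the defaults, and what the synthetic results
do and do not establish.

## Protocol and windows

The measurement protocol is five contiguous 4-minute phases —
relax1, stress1, relax2, stress2, relax3 — for 20 minutes total.  HRV is
summarised over six half-open analysis windows: a 30-s baseline at the
recording onset, and a 3-min sample per phase starting 20 s after phase
onset.  The recording opens with relax1, so the baseline window is the
opening segment of relax1's span; it necessarily shares the 10-s
interval [20 s, 30 s) with relax1's analysis window.  Intervals are
assigned to windows by their *end* time, which prevents double counting
at boundaries.

## Synthetic cohort generator

### RR tachogram model

Per subject, instantaneous RR is

    RR(t) = 60 / HR_level(t) + s · sin(2π f_resp t + φ) + e_k ,

with beats placed recursively (t_{k+1} = t_k + RR(t_k)).  `HR_level` is
piecewise constant over the six protocol segments with 10-s linear ramps
at transitions (real autonomic transitions have no published model; a
short ramp keeps the analysis windows stationary).  The sinusoid stands
in for respiratory sinus arrhythmia (f_resp ~ U(0.2, 0.3) Hz,
uncontrolled breathing); `e_k` is AR(1) beat-to-beat noise.  This is the
minimal model whose short-term (RMSSD) and total (SDNN) variability are
separately tunable.

Given per-subject target amplitudes R (RMSSD) and S (SDNN), the
calibration solves

    S² ≈ s²/2 + c(φ, n)·σ²          (window variance)
    R² ≈ 2 s² sin²(π f T) + 2σ²(1−φ)  (successive differences)

for the sinusoid amplitude s (fixed to supply half of R²), the AR(1)
stationary s.d. σ and coefficient φ, where c(φ, n) is the finite-window
variance bias of an AR(1) over the ~n beats of the 30-s baseline window.
Monte-Carlo checks put realized window metrics within ~1 % of the
targets in expectation; cohort-level means carry a further 1–2 %
downward drift from the layered draws, well inside the 5 % calibration
band, but single samples of a few hundred subjects can stray ±4 %
because the amplitude distribution is strongly right-skewed
(between-subject CV ≈ 0.65, matched to the study population).

### Group and cluster calibration

Baseline RRmean is drawn per subject from the published group
distributions (FM 0.844 ± 0.134 s; controls 0.934 ± 0.118 s).  Because
heart rate is averaged as mean instantaneous 60/RR, the group-mean HR
exceeds 60/RRmean by the between-subject relative variance (Jensen's
inequality); with the published spreads this reproduces the published
group HR means (72.3 / 64.5 bpm) without separate tuning — the same
signature that motivated adopting the instantaneous-HR convention.

Phase levels are built from the control template (phase-minus-baseline
HR deltas taken from the published control means) plus additive
FM-by-phase interaction terms whose defaults equal the published
covariate-adjusted model coefficients (e.g. −4.41 bpm at stress2).
Cluster structure enters as per-cluster deviations on the stress-phase
interactions, baseline-RR offsets, and HRV amplitude scales, all
re-centred with the configured cluster proportions (weighted mean zero /
one) so the group-level truth is exact under any cluster mix.  Default
cluster ordering follows the study's phenotypes: cluster 1
control-like (slow baseline HR, high HRV, full reactivity), cluster 3
most affected, with a stronger attenuation at the repeated stressor.
Cluster allocation is deterministic (largest remainder), so the default
51-patient cohort splits 9/21/21 exactly.

Questionnaire scores (FIQ items and total, PCS, PSS, STAI-A/B) are
drawn from cluster-graded normal distributions clipped to instrument
ranges; anxiety- and depression-type items rise from cluster 1 to 3.
The magnitudes are free configuration (the study reports significance
patterns, not means).  Subjective ratings (0–10 NRS) at the six protocol
timepoints add +2 to stress ratings after each stressor and, by default,
no phase effect on pain.  Covariates (age, BMI, smoking, physical
activity) use the published group statistics; a small missingness rate
on the activity score reproduces the covariate-complete subset size.
Within-subject correlation between questionnaires and HRV arises only
through cluster membership — a deliberate modelling choice, since the
study gives no finer dependence structure.

### ECG synthesis and contamination

Each beat contributes a Ricker (negative-second-derivative Gaussian)
deflection of width 80 ms and amplitude 1 mV, peaking exactly at the
beat time; an optional low-frequency T wave is off by default.  The
surface-EMG recording condition adds (i) Gaussian noise bandpassed to
20–450 Hz and scaled so the 10–40 Hz QRS-band SNR equals a configured
value (default 0 dB), (ii) mains sinusoids at 50 Hz plus two harmonics
with amplitudes (2, 1, 0.5) mV and random phases — large enough to
dominate the raw spectrum — and (iii) slow sinusoidal drift
(0.5 mV, 30-s period).  The arithmetic-stressor constants (14 series of
ten digits, four false feedbacks, 60 dB masking noise) are recorded as
protocol metadata only.

What the generator does **not** emulate: ectopic beats and arrhythmia,
morphological ECG variation (P/QRS/T shape changes, electrode artifacts,
movement bursts), non-stationary EMG activity coupled to the task, and
any direct questionnaire–HRV correlation beyond cluster membership.
Passing tests therefore demonstrate correctness of the pipeline's
algorithms under a controlled, physiologically plausible signal model —
not field performance on clinical recordings.

## Extraction chain

`detrend` removes the mean (optionally a linear trend).  Mains peaks are
found automatically: a candidate frequency is flagged when its 1-Hz band
holds more than 3× the mean power of the flanking 0.5-Hz bands (the
visual inspection of the original workflow, made reproducible; explicit
band lists remain available).  `flatten_noise_band` sets each FFT bin in
the flagged band to the flank-level magnitude with phases preserved —
bands at or below flank level are left untouched, so the operation never
injects power, is exactly idempotent, and conserves out-of-band power to
round-off.  A 3rd-order Butterworth bandpass to 10–40 Hz follows,
applied forward–backward so beat times are not lag-shifted (a causal
single pass is available).

Single-channel PCA denoising uses time-delay embedding with lag 1 and
dimension equal to one full QRS width (80 ms of samples).  The leading
principal component then captures the QRS shape, and a rank-1
reconstruction by diagonal averaging suppresses broadband EMG noise;
at the default noise level this raises the QRS-band SNR of the signal
path while shrinking the noise path.  Shorter embeddings (e.g. 25 ms)
span only part of the complex and measurably degrade beat/noise
separation.  A cross-channel PCA mode exists for multichannel input.

QRS detection squares the isolated signal, integrates over a 100-ms
moving window (matching the QRS energy support), picks candidate peaks
at least 250 ms apart, and keeps those above 0.5× the 90th percentile of
candidate heights.  A rhythm-consistency pass then (a) fills RR gaps
longer than 1.6× the local median RR with the rejected candidate that
maximises height weighted by a Gaussian prior on the expected beat
position (s.d. 12 % of the local RR), and (b) prunes intervals shorter
than 0.55× the local median by dropping the weaker bounding peak.  Beats
are finally timestamped at the signal maximum within ±40 ms of the
energy peak.  On 20-min recordings at the default contamination this
yields ≥ 99 % beat sensitivity and positive predictive value with ~1 ms
median RR error; without the rhythm pass no threshold on the energy
statistic reaches that operating point.  RR cleaning flags intervals
outside [0.3, 2.0] s or deviating > 30 % from the median of their
5-interval neighbourhood; flagged intervals are excluded from all
metrics and break the RMSSD difference chain.  Channel selection scores
a trial extraction per channel by RR coefficient of variation, ties
broken by QRS-band power fraction, then index.

## HRV metrics

HR is the mean of instantaneous rates 60/RRᵢ (the convention whose
Jensen signature matches the published tables; 60/RRmean is available),
RRmean the arithmetic mean, RMSSD the root mean square of successive
differences across consecutive *accepted* intervals, SDNN the sample
standard deviation (n−1).  Internal units are seconds; ms converters are
provided.  Windows with fewer than three beats yield missing values,
never zeros.  Reactivity is the stress2-minus-baseline change in HR and
RRmean.

## GLS reactivity models

The long table holds one row per subject × phase (relax1 reference),
with the subject's baseline value of the same outcome as a covariate;
the adjusted variant adds BMI, smoking and physical activity, dropping
covariate-incomplete subjects listwise.  Estimation is feasible GLS with
an exchangeable (compound-symmetric) within-subject correlation — the
minimal structure that justifies GLS over OLS for repeated measures:
OLS, a moment estimate of ρ from residual cross-products, closed-form
blockwise whitening (the exchangeable square root has a rank-one
correction, so no matrix factorisation is needed), iterated to
|Δρ| < 1e-6 (max 50).  Wald intervals use a t reference with n−p
degrees of freedom; the published interval convention is unrecoverable,
and residual-df intervals are the conservative default.  ρ = 0
reproduces OLS exactly (asserted to 1e-10), and the fixed-ρ solve is
cross-checked against an independent GLS implementation with the
covariance supplied.  Under a null simulation (ρ = 0.3, 51 + 31
subjects) the stress2-interaction Wald test holds its 5 % level within
±2 %; with the generator's default truth the mean recovered stress2
coefficient is within 0.5 bpm of −4.41 over 200 cohorts.  Group
descriptives report both Student's t and Mann–Whitney (conventions in
this literature disagree), and 2×2 covariate tables use the
Yates-corrected χ² — the correction choice is pinned by reproducing the
published p = 0.091 (smoking) and p = 0.386 (activity) to three
decimals from the printed counts.

## Clustering

Candidate configurations obey the sample-size rule n ≥ 10·d·k.  The
default `paper` mode reproduces the published feasible set for ~50
patients and two candidate variables (both variables at k = 2; each
single variable at k = 2 and 3); `rule` mode enumerates the inequality
literally (which would also admit k = 4, 5 at d = 1 — the source applied
the rule as the smaller set, and both readings are exposed).  Variables
are z-scored (sample s.d.); k-means uses k-means++ with 100 restarts,
keeping the minimum-WSS solution, deterministic by seed (the engine is
scikit-learn's; tests verify global optimality against exhaustive
partition enumeration on small sets).  The minimum-total-WSS
configuration is selected, ties broken by smaller d then smaller k;
comparing WSS across different d on z-scored spaces is scale-sensitive
and inherited from the published procedure.  Selected clusters are
relabelled 1..k by ascending mean baseline HR, making all reports
invariant to label permutation.  Characterisation runs ANOVA + Tukey HSD
across clusters per questionnaire variable (variables with > 20 %
missingness are excluded — the source's "high percentage", quantified)
and refits trajectories with the sparse GLS
`variable = cluster × time + baseline` (cluster 1 reference).

Cluster-recovery checks use three 1-D reactivity modes with sizes
9/21/21.  An adjusted-Rand-index ≥ 0.9 criterion is information-
theoretically out of reach at 2-s.d. mode separation (the Bayes
misclassification rate between adjacent Gaussian modes is ~16 %), so the
well-separated construction uses 6 s.d.; there both ARI recovery and
minimum-WSS selection of (ΔRRmean, k = 3) succeed in ≥ 95 % of
replicates.

## Problem sizes and numerical choices

The test suite and the acceptance script scale their simulations to what
the checks need: calibration means over 1000–1500 subjects per group
(truth level, no waveforms), extraction fidelity over 8–20 full
recordings at fs = 1000 Hz, GLS recovery over 60–200 cohorts at truth
level, 1000 null replicates, 100 clustering replicates, and end-to-end
determinism on a 28-subject cohort at fs = 250 Hz.  All randomness
derives from a single master seed through spawned seed sequences (one
per subject, sub-streams per stage), so cohort generation and the full
pipeline are bit-reproducible; table writers use fixed float formats so
reruns are byte-identical.  Degenerate inputs are defined rather than
accidental: zero variability amplitudes give a metronomic heart, empty
windows give missing metrics, zero-variance z-transforms and
rank-deficient design matrices raise informative errors, and degenerate
2×2 tables yield flagged NaN results.

## Known limitations

Single-channel EDF writing is a minimal format implementation (validated
round-trip against an independent reader); EDF reading requires the
optional mne dependency.  The real-data entry points (delimited/EDF
signal readers, subject tables) are provided, but the turnkey pipeline
driver covers synthetic mode; real recordings should be driven through
the library stages directly.  The GLS assumes exchangeable within-
subject correlation (AR(1)-by-phase is not implemented) and homoscedastic
groups.  Frequency-domain and nonlinear HRV measures, ectopic-beat
classification, and ECG morphology beyond beat timing are out of scope.
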