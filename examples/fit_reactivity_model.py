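"""Fit the group x time GLS reactivity model on a simulated cohort.

Uses generator-truth HRV summaries (bypassing signal extraction) for a
default-sized cohort of 51 FM patients and 31 controls, and prints the
heart-rate model coefficients.  The FM : stress2 interaction estimates
how much smaller the FM patients' heart-rate response to the second
stressor is; its generator truth is -4.41 bpm.
"""

import warnings

from hrvreact import models
from hrvreact.simulate import SimulationConfig, generate_cohort

cohort = generate_cohort(SimulationConfig(master_seed=2024))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    long = models.build_long_table(
        cohort.truth_summaries, cohort.subjects, "hr_bpm"
    )
print(f"long table: {len(long)} rows "
      f"({long['subject_id'].nunique()} subjects x 5 phases)")

fit = models.fit_gls(long)
print(f"exchangeable rho = {fit.rho:.3f}; n = {fit.n_obs}\n")
print(f"{'term':<28s} {'estimate':>9s} {'95% CI':>20s} {'p':>8s}")
for _, row in fit.params.iterrows():
    ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
    print(f"{row['term']:<28s} {row['estimate']:9.2f} {ci:>20s} "
          f"{row['p']:8.3g}")
# One cohort is one draw: the stress2 interaction should fall within a
# bpm or so of -4.41, with the stress time effects near +11 to +13 bpm.
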