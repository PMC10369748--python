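"""Three-strategy bias comparison under a collider + pleiotropy covariate.

Simulates cohorts where a covariate P is both a collider (adjusting for it
opens a spurious path between the exposure's genetic score and the outcome's
confounders) and a pleiotropy channel (the exposure's instruments reach the
outcome through P). Each replicate estimates the exposure's causal effect
(truth = 1) three ways and the study reports the mean bias.

A small run for illustration; scale --reps/--n up for publication-grade
Monte-Carlo error (e.g. reps=1000, n=250000).
"""

from mviv import DGPConfig, run_study

config = DGPConfig(n_individuals=20_000, structure_variant="pleiotropic", seed=7)
report = run_study(config, reps=30, seed=7)

print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:+.4f}"))
print(
    "\nReading: uv_unadjusted is biased up (~+1) by the pleiotropy channel,\n"
    "uv_adjusted is biased down (~-0.45) by collider adjustment, and the\n"
    "multivariable model (mv_adjusted) attenuates most of both biases."
)
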