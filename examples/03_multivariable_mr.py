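"""Multivariable two-sample MR with a covariate exposure.

Uses the exposure + covariate + outcome fixture tables: instruments are
variants associated with either exposure, and the multivariable estimators
return the exposure's direct effect conditional on the covariate, together
with each exposure's conditional F-statistic (instrument strength given the
other exposure).
"""

from mviv import PipelineConfig, mvmr_pipeline, results_to_frame, simulate_sumstats_fixture

exposure, _, covariate, outcome = simulate_sumstats_fixture(
    n_variants=120, n_palindromic=0, flip_fraction=0.3, seed=15, n_significant=60,
)

results, provenance, harmonised = mvmr_pipeline(
    exposure, covariate, outcome, PipelineConfig(n_boot=300, seed=2))

frame = results_to_frame(results)
cols = ["method", "exposure", "estimate", "se", "ci_low", "ci_high", "conditional_f"]
print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print(
    "\nReading: the 'exposure' rows are direct effects conditional on the\n"
    "covariate; a conditional F well above ~10 indicates the instruments\n"
    "retain strength once the covariate's associations are partialled out."
)
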