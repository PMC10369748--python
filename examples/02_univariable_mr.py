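"""Univariable two-sample MR on synthetic summary statistics.

Builds a fixture with a known true effect (0.5 on the outcome scale), mixed
allele orientations and five palindromic variants, runs the full applied
workflow — genome-wide selection, FIQT winner's-curse correction, clumping,
harmonisation, four estimators — and then shows what the FIQT correction
buys on a second fixture whose top hits carry inflated effect sizes.
"""

from mviv import PipelineConfig, mr_pipeline, results_to_frame, simulate_sumstats_fixture

exposure, _, _, outcome = simulate_sumstats_fixture(
    n_variants=120, n_palindromic=5, flip_fraction=0.5, seed=71, n_significant=60,
)
print(f"true effect built into the fixture: {outcome.meta['true_effect']}")

results, provenance, harmonised = mr_pipeline(
    exposure, outcome, PipelineConfig(n_boot=500, seed=1))

frame = results_to_frame(results)
cols = ["method", "estimate", "se", "ci_low", "ci_high", "n_snps"]
print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:+.4f}"))
print(f"\nvariants dropped per stage: {provenance}")
print(
    "\nReading: the estimators agree and the IVW interval covers the true\n"
    "0.5; the provenance counts the not-significant, palindromic and\n"
    "flipped records the pipeline handled on the way.\n"
)

# winner's curse: inflate 20% of the significant exposure hits and compare
cursed, _, _, out2 = simulate_sumstats_fixture(
    n_variants=120, n_palindromic=0, flip_fraction=0.0, seed=13,
    n_significant=60, winners_curse_fraction=0.5,
)
est_on = mr_pipeline(cursed, out2, PipelineConfig(fiqt=True))[0][0]
est_off = mr_pipeline(cursed, out2, PipelineConfig(fiqt=False))[0][0]
print("winner's-curse fixture (half the hits inflated), IVW estimates:")
print(f"  without FIQT: {est_off.estimate:+.4f}   with FIQT: {est_on.estimate:+.4f}"
      f"   (truth {out2.meta['true_effect']})")
print("FIQT moves the estimate back toward the truth by shrinking the\n"
      "selected exposure z-scores.")
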