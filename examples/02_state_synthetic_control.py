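"""State-level synthetic control with placebo inference.

Simulates a 45-state panel in which the treated state's policy raises MMR
coverage by 3.3 percentage points from 2016 on, fits the synthetic control,
and runs the placebo permutation test.  The effect size is the pre-to-post
change of the treated state relative to its synthetic control; the placebo
rank says how extreme that effect is among all states.
"""

from vaxpolicy import SimConfig, fit_synthetic_control, run_placebo_tests, simulate_state_panel

TAU = {"coverage": 3.3, "nonmedical": -2.4, "medical": 0.4}
BASELINE = {"coverage": (88.0, 2.5), "nonmedical": (8.0, 1.3), "medical": (3.0, 0.2)}

panel = simulate_state_panel(
    SimConfig(n_states=45, seed=1, tau=TAU, baseline=BASELINE, noise_sd=0.3))

result = fit_synthetic_control(panel, "mmr", predictors=[], treated="CA")
print(f"estimated policy effect on MMR coverage: {result.effect_size:+.2f} pp "
      f"(injected: +3.30 pp)")
print(f"prepolicy fit (MSPE): {result.weights.pre_mspe:.3f}")
top = sorted(result.donor_contributions.items(), key=lambda kv: -kv[1])[:4]
print("largest donor weights:", ", ".join(f"{d}={w:.2f}" for d, w in top))

placebo = run_placebo_tests(panel, "mmr", [], "CA", treated_result=result)
print(f"placebo rank: {placebo.rank} of {placebo.n_evaluated} states "
      f"(top {placebo.percentile:.1f}%) -> meaningful={placebo.meaningful}")
# rank 1-2 of 45 puts the treated state inside the prespecified top-5% rule:
# the effect is larger than essentially all no-policy placebo effects.
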