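"""Simulate a protective dietary exposure and estimate its causal effect.

Generates summary statistics for 41 instruments under a true causal
effect of -0.5 on the log-odds scale (the protective direction), then
runs the three core estimators.  All three betas should sit near -0.5
with overlapping confidence intervals.
"""

from mrdiet import egger, ivw, scenario_suite, simulate_harmonized, wald_ratios, weighted_median

truth = scenario_suite()["causal_protective"]
hset, effects = simulate_harmonized(truth)
ratios = wald_ratios(hset)

print(f"true causal effect: {truth.beta_true}, instruments: {truth.J}")
for est in (ivw(ratios, "fixed"), ivw(ratios, "mre"),
            egger(hset).slope, weighted_median(ratios)):
    print(f"{est.method:>14}: beta={est.beta:+.3f}  se={est.se:.3f}  "
          f"OR={est.or_value:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})  p={est.pvalue:.2e}")
print("Each beta is the log odds-ratio per unit of weekly exposure; "
      "OR < 1 means the exposure is protective.")
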