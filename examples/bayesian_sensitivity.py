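"""Two-step Bayesian IPTW on a study-like synthetic cohort.

Samples the propensity-model posterior with NUTS (Cauchy(logit 0.126, 2.5)
intercept prior, uniform(-10,10) slopes), reruns the weighted outcome models
for every draw, and averages the per-draw effects — propagating propensity
uncertainty that the plain frequentist IPTW ignores.  Uses half the full
draw budget to stay quick; the full analysis uses 4 chains x 2,500 draws.
"""

from iptwkit import default_config, generate_cohort, two_step_bayes_ate

cohort = generate_cohort(default_config(n=1000, seed=42))
print(f"cohort: n={cohort.n}, exposed={cohort.exposure.sum()}, "
      f"cases={cohort.outcome.sum()} (true RD 0.07)")

result = two_step_bayes_ate(cohort, chains=4, draws=1250, warmup=1000, seed=42)
rd, rr = result.rd, result.rr
print(f"posterior-mean aRD = {rd.mean:.3f}  "
      f"(94% HDI {rd.hdi_low:.3f}, {rd.hdi_high:.3f})")
print(f"posterior-mean rRR = {rr.mean:.2f}  "
      f"(94% HDI {rr.hdi_low:.2f}, {rr.hdi_high:.2f})")
print(f"max split-R-hat = {rd.r_hat:.4f}  (<= 1.01 indicates convergence)")
print(f"degenerate draws dropped: {rd.dropped_draws} of "
      f"{rd.n_draws + rd.dropped_draws}")
print("-> with only ~23 exposed, propensity uncertainty widens the interval "
      "relative to the fixed-weight frequentist analysis.")
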