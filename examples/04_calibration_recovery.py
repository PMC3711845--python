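"""Exercising the calibration stages on synthetic patient-level records.

The cost and survival inputs were originally fitted from administrative
data that cannot be shipped. This script generates synthetic stand-ins
with the same structure — gamma interval costs (study size n = 68) and
right-censored Weibull survival — and shows what maximum-likelihood
refits recover at the study's sample size versus a large registry.
"""

import brcascreen as bs
from brcascreen import synthetic

spec = bs.load_calibrated_spec()
params = spec.mean_parameter_set()

gamma_local = spec.costs["treat_local"]
k, theta = gamma_local.params
print(f"generating local-stage treatment costs from Gamma(k={k:.2f}, "
      f"theta={theta:,.0f}), mean ${k * theta:,.0f}")
for n in (68, 10_000):
    recs = synthetic.generate_cost_records({"local": 1.0},
                                           {"local": gamma_local},
                                           n=n, seed=2024)
    fit = synthetic.fit_gamma_mle(recs, "local")
    print(f"  n={n:>6,}: fitted mean ${fit.mean():,.0f}, "
          f"shape {fit.params[0]:.2f}")

print()
w = params.survival["local"]
print(f"generating local-stage survival from Weibull(shape={w.shape:.3f}, "
      f"scale={w.scale:.1f} yr), censored at 8 years of follow-up")
recs = synthetic.generate_survival_records({"local": w}, censor_time=8.0,
                                           n=10_000, seed=7)
fit = synthetic.fit_weibull_mle(recs, "local")
print(f"  {(~recs.event).mean():.0%} censored; fitted "
      f"S(5)={fit.survival(5.0):.3f} (target 0.968), "
      f"S(10)={fit.survival(10.0):.3f} (target 0.906)")

# At n = 68 the fitted mean wobbles by thousands of dollars — the wide
# printed confidence intervals on treatment costs are a direct
# consequence of the small costing sample, and the probabilistic
# sensitivity analysis propagates exactly that uncertainty.
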