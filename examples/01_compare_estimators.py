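"""Compare every estimator of the treatment effect on one dataset.

Simulates a claims-like dataset with strong unmeasured selection
(rho = 0.721): unobservables that push subjects toward the new treatment
also push spending up.  OLS is badly biased upward; the IV estimators and
the likelihood-based MLE correct the bias with very different precision.
"""

from ivtreat import (
    ErrorSpec,
    StructuralParams,
    first_stage_F,
    fit_2sls,
    fit_2sps,
    fit_2sri,
    fit_mle,
    fit_ols,
    simulate_dataset,
)

TRUTH = -0.793  # generating treatment effect on the log-cost scale

params = StructuralParams.collapsed(beta1=TRUTH, rho=0.721, sigma_y=1.5)
errors = ErrorSpec("normal", rho=0.721, sigma_y=1.5)
data = simulate_dataset(params, errors, n=7835, seed=1)

print(f"n = {data.n}, treated share = {data.z.mean():.3f}, true beta1 = {TRUTH}")
f = first_stage_F(data)
print(f"first-stage F = {f.F:.2f} ({'weak' if f.weak else 'adequate'} instrument)\n")

print(f"{'method':8s} {'beta1':>8s} {'SE':>7s}")
for name, fit in [
    ("OLS", fit_ols(data)),
    ("2SLS", fit_2sls(data)),
    ("2SPS", fit_2sps(data)),
    ("2SRI", fit_2sri(data)),
    ("MLE", fit_mle(data)),
]:
    print(f"{name:8s} {fit.beta1:8.3f} {fit.se['beta1']:7.3f}")

print(
    "\nOLS overstates beta1 by roughly rho*sigma_y*(selection intensity); the\n"
    "two-stage estimators are unbiased but pay for the weak-ish instrument\n"
    "with large SEs, while the MLE leans on the bivariate-normal assumption\n"
    "to recover beta1 with near-OLS precision."
)
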