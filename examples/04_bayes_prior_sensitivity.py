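"""Bayesian estimation and sensitivity to the prior on rho.

The extended-Beta prior (rho+1)/2 ~ Beta(nu, nu) spans everything from
uniform on (-1, 1) (nu = 1, prior variance 1/3) to a spike at rho = 0
(large nu).  Sweeping the prior variance shows the posterior mean of beta1
traveling between the OLS answer (selection ignored) and the MLE answer
(selection estimated), while the ATE summary barely moves.
"""

from ivtreat import (
    ErrorSpec,
    PriorSpec,
    StructuralParams,
    fit_bayes,
    fit_mle,
    fit_ols,
    prior_sensitivity_sweep,
    simulate_dataset,
)

params = StructuralParams.collapsed(rho=0.721, sigma_y=1.5)
data = simulate_dataset(params, ErrorSpec("normal", 0.721, 1.5), 2000, seed=4)

post = fit_bayes(data, PriorSpec(), iters=3000, warmup=1000, chains=2, seed=5)
print("uniform-prior posterior (mean, sd):")
print(post.summary().loc[["beta1", "rho", "sigma_y"], ["mean", "sd", "rhat"]].round(3))
print(f"MLE beta1 = {fit_mle(data).beta1:.3f}, OLS beta1 = {fit_ols(data).beta1:.3f}")

table = prior_sensitivity_sweep(
    data, [1e-4 / 3, 0.04, 1 / 3, 0.9], iters=2000, warmup=800, chains=1, seed=6
)
print("\nprior variance -> posterior means:")
print(table[["prior_variance", "nu", "beta1_mean", "ate_mean", "rho_mean"]].round(3))
print(
    "\nWith a near point-mass prior at rho = 0 the posterior mean of beta1\n"
    "reproduces OLS; as the prior loosens it migrates to the MLE. The ATE\n"
    "column varies far less: the data pin the conditional-mean contrast\n"
    "regardless of how credit is split between beta1 and selection."
)
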