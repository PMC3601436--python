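"""Profile likelihood of rho and the exclusion-restriction test.

The selection correlation rho is the crux of the model: profiling the
log-likelihood over rho checks that the MLE is a unique interior optimum.
Because the likelihood identifies the model even with instruments in the
outcome equation, the exclusion restriction (beta3 = 0) becomes testable --
under the bivariate-normal error assumption.
"""

import numpy as np

from ivtreat import (
    ErrorSpec,
    StructuralParams,
    profile_rho,
    simulate_dataset,
    test_exclusion,
)

params = StructuralParams.collapsed(rho=0.721, sigma_y=1.5, beta3=0.0)
data = simulate_dataset(params, ErrorSpec("normal", 0.721, 1.5), 7835, seed=3)

curve = profile_rho(data, np.arange(0.4, 0.91, 0.05))
print("rho    profile loglik")
for r, ll in zip(curve.rho_grid, curve.loglik):
    marker = "  <- max" if r == curve.argmax else ""
    print(f"{r:5.2f}  {ll:12.2f}{marker}")
print(f"\nprofile argmax = {curve.argmax:.2f} (generating value 0.721)")

rep = test_exclusion(data)
print(
    f"\nexclusion test: beta3-hat = {float(rep.beta3.iloc[0]):+.4f} "
    f"(SE {float(rep.se.iloc[0]):.4f}), Wald = {rep.wald:.2f}, "
    f"p = {rep.p_value:.3f} -> {'reject' if rep.reject else 'retain'} H0: beta3 = 0"
)
print(
    "\nA single interior peak supports the likelihood analysis; retaining\n"
    "beta3 = 0 is consistent with the instrument having no direct effect on\n"
    "spending (the data were generated that way)."
)
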