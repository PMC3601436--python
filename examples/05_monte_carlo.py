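"""A small Monte-Carlo study of the exclusion-restriction test.

Reruns a scaled-down version of the operating-characteristics study: size
of the likelihood-based test of beta3 = 0 when the exclusion restriction
holds, and its power when the instrument leaks directly into the outcome.
(The full study uses n = 7835 and hundreds of replicates; this demo is
deliberately small.)
"""

from ivtreat import ScenarioSpec, run_scenario

for beta3, label in [(0.0, "exclusion holds (size)"), (0.144, "full violation (power)")]:
    sc = ScenarioSpec(
        error_family="normal",
        beta3=beta3,
        sigma_y=1.57,  # close to the calibrated study value
        n=2000,
        reps=60,
        base_seed=11,
        estimators=("mle_exclusion",),
    )
    m = run_scenario(sc)
    t = m.table.loc[("mle_exclusion", "beta3")]
    print(
        f"beta3 = {beta3:5.3f} [{label}]: bias {t['bias']:+.4f}, "
        f"RMSE {t['rmse']:.4f}, coverage {t['coverage']:.2f}, "
        f"rejection rate {t['power']:.2f} (+-{t['power_mc_se']:.2f})"
    )

print(
    "\nAt beta3 = 0 the rejection rate sits near the nominal 0.05; at\n"
    "beta3 = 0.144 (a direct instrument effect as large as its selection\n"
    "effect) the test detects the violation essentially always, though at\n"
    "this reduced n the power is lower than in the full-size study."
)
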