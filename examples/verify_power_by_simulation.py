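"""Check a solved design's power empirically with the Monte-Carlo engine.

Replays the continuous worked design (n10 = 55, n11 = 28, n01 = 55) under
its own data-generating process and under a zero-change null, and compares
the empirical rejection rates to the design-stage approximation (0.7955)
and the nominal level (0.05).
"""

from panelpower import MeansTruth, empirical_power

truth = MeansTruth(mu_t=3.0, mu_t1=0.0, sigma_x2=100, sigma_y2=75, rho=0.9)
null = MeansTruth(mu_t=0.0, mu_t1=0.0, sigma_x2=100, sigma_y2=75, rho=0.9)

power = empirical_power(
    55, 28, 55, net_truth=truth, sided="one", alpha=0.05,
    direction=1, reps=10_000, seed=20240905,
)["net"]
size = empirical_power(
    55, 28, 55, net_truth=null, sided="one", alpha=0.05,
    direction=1, reps=10_000, seed=20240906,
)["net"]

print(f"empirical power : {power.power_hat:.4f} +/- {power.mc_se:.4f} "
      f"(design approximation 0.7955)")
print(f"empirical size  : {size.power_hat:.4f} +/- {size.mc_se:.4f} "
      f"(nominal level 0.05)")

# Both should sit within about three Monte-Carlo standard errors of their
# reference values; the power target (0.80) is met up to the 2-decimal
# rounding built into the stop rule.
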