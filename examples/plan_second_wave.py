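"""Size the second wave when the first wave is already in the field.

Between waves the first-wave size n_t is fixed; only the overlap n11 and
the second-wave total n_t+1 remain free.  The closed-form solver inverts
the net-change variance for n_t+1 directly.
"""

from panelpower import NetChangeSpecMeans, TestParams, n_next_wave_means

spec = NetChangeSpecMeans(
    delta=3, sigma_x2=100, sigma_y2=100, rho=0.8,
    test=TestParams(alpha=0.05, power=0.80, sided="two"),
)

sol = n_next_wave_means(n_t=150, n_11=28, spec=spec)
print(f"required n_t+1 = {sol.n} (raw formula value {sol.n_raw:.2f})")
print(f"feasibility margin (denominator): {sol.components['denominator']:.2f}")

# The raw value makes the net-change estimator variance hit delta^2 / C
# exactly, where C is the critical factor; the ceiling is applied last.
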