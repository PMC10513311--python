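"""Size a two-wave panel to detect net and gross change in a continuous outcome.

The survey must detect a net change of 3 units across waves (population
variances 100 and 75, paired correlation 0.9) and a gross, within-person
change of 3 units in the overlap panel (common paired variance 200), each
with one-sided alpha = 0.05 and 80% power.
"""

from panelpower import (
    DesignOptions,
    GrossChangeSpecMeans,
    NetChangeSpecMeans,
    TestParams,
    sequential_search,
)

one_sided = TestParams(alpha=0.05, power=0.80, sided="one")
net = NetChangeSpecMeans(delta=3, sigma_x2=100, sigma_y2=75, rho=0.9, test=one_sided)
gross = GrossChangeSpecMeans(delta_gross=3, sigma_o2=200, rho=0.9, test=one_sided)

result = sequential_search(gross, net, DesignOptions(theta=0.5))

print(f"overlap panel (gross requirement): n11 = {result.n11}")
print(f"sequential search: {result.iterations} iterations")
print(f"wave-t sample: n_t = {result.n_t}  (fresh n10 = {result.n10})")
print(f"overlap fraction: gamma = {result.gamma:.2f}")
print(f"approximate power: net {result.achieved_power_net:.4f}, "
      f"gross {result.achieved_power_gross:.4f}")

# n11 units must be interviewed in both waves; the rest of each wave is fresh
# sample. The net power is the normal approximation at the stopping design.
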