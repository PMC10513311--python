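"""Size a two-wave panel for a binary outcome.

Net change: the population proportion moves from 0.50 to 0.70, with a
joint proportion of 0.45 holding the characteristic at both waves.
Gross change: within the overlap panel the proportion moves from 0.50 to
0.80 (joint 0.45).  Both tests one-sided at alpha = 0.05 with 80% power.
"""

from panelpower import (
    DesignOptions,
    GrossChangeSpecProps,
    NetChangeSpecProps,
    TestParams,
    sequential_search,
)

one_sided = TestParams(alpha=0.05, power=0.80, sided="one")
net = NetChangeSpecProps(p_t=0.5, p_t1=0.7, p_xy=0.45, test=one_sided)
gross = GrossChangeSpecProps(p_t=0.5, p_t1=0.8, p_xy=0.45, test=one_sided)

result = sequential_search(gross, net, DesignOptions(theta=0.5))

print(f"overlap panel (gross requirement): n11 = {result.n11}")
print(f"sequential search: {result.iterations} iterations")
print(f"wave-t sample: n_t = {result.n_t}  (fresh n10 = {result.n10})")
print(f"overlap fraction: gamma = {result.gamma:.2f}")

# With completion rates below 1 the fielded sizes grow; e.g. panel rate 0.8
# and fresh rate 0.7:
from panelpower import inflate_for_nonresponse

fielded = inflate_for_nonresponse(result, rr11=0.8, rr10=0.7)
print(f"fielded sizes at 80%/70% completion: n11 = {fielded.n11_inflated}, "
      f"n10 = {fielded.n10_inflated}")
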