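"""Passive compensation in an integrate-and-fire neuron.

A 30% reduction in synaptic conductance can be compensated by a 21% drop in
leak conductance (higher input resistance) plus a 5 mV depolarization of
rest: the normalized depolarization curve then coincides with control.
"""

import numpy as np

from neurocost import biophys

res = biophys.if_compensation_curves(grid=np.linspace(0, 1, 11))
print("g/g0    control   food-restricted (compensated)")
for f, uc, uf in zip(res["grid"], res["control"], res["food_restricted"]):
    print(f"{f:4.1f}    {uc:7.4f}   {uf:7.4f}")
print(f"\nmax |deviation| = {100 * res['max_abs_deviation']:.2f}% of the "
      "distance to spike threshold")
print(
    "Near-coincidence of the two curves shows spike output is preserved\n"
    "despite 30% less synaptic drive — the energy-saving compensation."
)
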