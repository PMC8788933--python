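"""Orientation tuning analysis of a synthetic imaging population.

Generates neuron x orientation x trial responses with known Gaussian
tuning, classifies grating responsiveness by BIC, fits constrained Gaussian
tuning curves and reports widths and orientation selectivity (OSI).
"""

import numpy as np

from neurocost import synth, tuning

orientations = np.arange(0.0, 180.0, 22.5)
pop = synth.gen_population_responses(
    n_neurons=30,
    stimuli=orientations,
    tuning_width_deg=28.0,
    response_cv=0.25,
    n_trials=10,
    seed=3,
)

widths, osis, n_resp = [], [], 0
for i in range(pop.n_neurons):
    responsive, dbic = tuning.bic_responsive(orientations, pop.responses[i])
    if not responsive:
        continue
    n_resp += 1
    means = pop.responses[i].mean(axis=1)
    fit = tuning.fit_orientation_gaussian(orientations, means)
    widths.append(fit.width_deg)
    osis.append(tuning.osi(orientations, means))

print(f"grating-responsive neurons: {n_resp}/{pop.n_neurons} (BIC >= 10)")
print(f"median tuning width sigma:  {np.median(widths):.1f} deg "
      f"(generator truth 28.0 deg)")
print(f"median OSI:                 {np.median(osis):.2f}")
print(
    "\nBroader widths at unchanged preferred orientations are the signature\n"
    "of reduced orientation selectivity under energy restriction."
)
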