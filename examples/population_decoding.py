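"""Leave-one-out maximum-likelihood decoding of stimulus identity.

Decodes grating orientation from a tuned synthetic population, compares
with an untuned (chance-level) population, and shows how trial noise
degrades fine orientation discrimination via simulated orientation sets.
"""

import numpy as np

from neurocost import decoding, synth, tuning

orientations = np.arange(0.0, 180.0, 15.0)  # 12 stimuli

tuned = synth.gen_population_responses(
    60, orientations, tuning_width_deg=30.0, response_cv=0.3, n_trials=20, seed=4
)
untuned = synth.gen_population_responses(
    60, orientations, tuning_width_deg=np.inf, response_cv=0.3, n_trials=20, seed=5
)

acc_tuned = decoding.loo_ml_decode(tuned, n_sample=50, n_resample=20, seed=6).accuracy
acc_unt = decoding.loo_ml_decode(untuned, n_sample=50, n_resample=20, seed=6).accuracy
print(f"tuned population accuracy:   {acc_tuned:.3f}")
print(f"untuned population accuracy: {acc_unt:.3f}  (chance = {1/12:.3f})")

# discrimination vs orientation spacing, from fitted tuning curves
fits = [
    tuning.TuningFit(0.05, 1.0, float(p), 25.0, 0.0, "single")
    for p in np.linspace(0, 180, 13)[:-1]
]
acc = decoding.simulate_orientation_decoding(
    fits, pooled_cv=0.5, spacings_deg=(7.5, 15.0, 30.0), n_trials=8, n_rep=20, seed=7
)
for spacing, a in sorted(acc.items()):
    print(f"spacing {spacing:5.1f} deg -> accuracy {a:.3f}")
print(
    "\nAccuracy falls as orientations get closer: noisy, broadly tuned\n"
    "populations lose fine discrimination first."
)
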