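# neurocost

Tools for studying how cortical neurons trade **coding precision for energy
savings**. When food is scarce, visual cortical neurons reduce the
conductance of their AMPA receptors — cutting the Na+/K+-ATPase cost of
synaptic transmission — and compensate with a higher input resistance
(leak conductance × 0.79) and a ~5 mV depolarized resting potential so that
spike output is preserved. The price is precision: the same compensations
amplify subthreshold noise, broaden orientation tuning, and blur fine
stimulus discrimination. `neurocost` implements the computational chain
needed to quantify this trade-off, end to end, on synthetic data with known
ground truth.

## What's inside

| module | contents |
| --- | --- |
| `neurocost.synth` | generators for current-clamp traces, binomial-channel mEPSC recordings, current-step relaxations, population response tensors and FRET ATP-sensor series — all pure functions of `(params, seed)` with full ground truth |
| `neurocost.biophys` | single-compartment Hodgkin–Huxley-type neuron (Nav m³h, fast delayed-rectifier Kv, slow stochastic Kv noise source, biexponential AMPAR synapse), the four group conditions, rheobase and input–output analysis, trial-to-trial CV at matched depolarization, and the passive integrate-and-fire compensation model |
| `neurocost.ephys` | spike detection and thresholds, spike clipping, grating responses, trial CV, double-exponential intrinsic fits (R_m, τ_m, C_m), mEPSC detection, binomial mean–variance (nonstationary fluctuation) analysis, paired-pulse ratio and 1/CV² |
| `neurocost.energetics` | ATP/s for synaptic signaling (1.42 Na+ correction, 3 Na+ per ATP), spiking (1.35 × 10¹¹ ATP · spike⁻¹ · cm⁻²) and rest (pump–leak balance formula), plus FRET decay-rate estimation |
| `neurocost.tuning` | ΔF/F, constrained Gaussian tuning fits R(θ) = C + R_p e^(−ang_ori(θ−θ_pref)²/2σ²), OSI = \|Σ R e^{2iθ}\| / Σ R, BIC responsiveness (ΔBIC ≥ 10), the ≥5 SD movie-responsiveness rule, and the Gaussian-noise model converting subthreshold tuning + trial CV into spike-probability tuning |
| `neurocost.decoding` | leave-one-out maximum-likelihood population decoding (Gaussian log-likelihoods summed across neurons), fine/coarse natural-scene decoding, pixel dissimilarity scores, and simulated orientation-set discrimination |
| `neurocost.pipeline` | YAML-configured multi-stage runs with seed substreams, manifests and reports |

## Worked example

Amplification of trial-to-trial variability by the two passive
compensations (`examples/hh_variability.py`, reduced trial count):

```
$ python examples/hh_variability.py
sigma0 (external noise SD at control rheobase): 0.0100 nS

group              CV       CV / control
control           0.0149   1.000
R_only            0.0172   1.153
Vrest_only        0.0176   1.180
food_restricted   0.0207   1.384
```

Raising input resistance alone (`R_only`) or depolarizing rest alone
(`Vrest_only`) each amplify the *same* noise source by ~15–20%; combined
(`food_restricted`) the CV rises by ~40–55% (the full-size run in
`scripts/acceptance.py` gives +55% at n = 150 trials). The drive is
matched across groups (same normalized depolarization), so the increase is
pure noise amplification, not a stimulus effect.

Single-channel conductance from mEPSC fluctuations
(`examples/mean_variance_mepsc.py`):

```
$ python examples/mean_variance_mepsc.py
detected 403 isolated events (4.92 Hz overall)
unitary current:          0.884 pA  (truth 1.0)
single-channel conductance: 12.6 pS
open channel number:      109.3   (truth 100)
```

The variance-vs-mean parabola σ² = iμ − μ²/N over the event decays
recovers the unitary current `i` from its initial slope and the open
channel count `N` from the mean amplitude — the measurement that localizes
the energy saving to single-channel AMPAR conductance.

Other examples: `orientation_tuning.py` (BIC responsiveness, Gaussian fits,
OSI), `population_decoding.py` (decoder vs chance, fine-discrimination
loss), `if_compensation.py` (the 30%-less-conductance compensation
identity), `energy_budget.py` (per-cell ATP table), `run_pipeline.py`
(configured end-to-end run).

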