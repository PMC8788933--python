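# Methods

This note documents the models, estimators, parameter choices and numerics
behind `neurocost`, and states what the synthetic-data generators do and do
not emulate.

## The scientific setting

Energy restriction changes three cell-intrinsic properties of layer 2/3
visual cortical neurons: AMPAR conductance falls (≈30% less synaptic
current), leak conductance falls to ≈79% of control (input resistance up
≈27%), and the resting potential depolarizes by ≈5 mV. The package
quantifies two consequences:

1. **Compensation** — spike output is preserved because the smaller synaptic
   conductance is amplified by the higher input resistance and has less
   distance to cover to threshold.
2. **Precision loss** — any voltage-dependent or input-proportional noise
   source is amplified by the same two changes, raising trial-to-trial
   subthreshold variability, broadening orientation tuning of spike output,
   and degrading fine stimulus discrimination.

## Conductance-based model neuron (`biophys`)

Single compartment, area 200 µm², specific capacitance 1 µF/cm²:

```
c_m dV/dt = −g_L(V−E_L) − ḡ_Na m³h(V−E_Na) − ḡ_Kf n_f⁴(V−E_K)
            − ḡ_Ks n_s⁴(V−E_K) − g_syn(t)(V−E_syn)
```

- **Leak**: g_L = 0.1 mS/cm² so τ_m = c_m/g_L = 10 ms (control); E_L = −70 mV.
- **Nav**: classic m³h rate functions with a +14 mV activation/inactivation
  shift, ḡ_Na = 50 mS/cm². The shift and conductance are set by
  `calibrate_channels`, a deterministic grid search whose targets are a
  spike threshold between −45 and −38 mV, a positive AP peak, and
  repolarization below threshold within 5 ms (brief afterhyperpolarization).
- **Fast delayed-rectifier Kv**: n⁴ with 4× accelerated classic rates and a
  +20 mV activation shift (ḡ_Kf = 6 mS/cm²). The right-shift makes it a
  genuine delayed rectifier — nearly silent below threshold — which
  matters: a subthreshold-activating Kv would dominate rheobase and destroy
  the passive compensation structure across groups.
- **Slow Kv (noise source)**: the original squid-axon n⁴ channel with
  unmodified classic rates. Its conductance is chosen by the calibration as
  the largest candidate (0.05–0.4 mS/cm²) that changes the AP amplitude by
  <5% when removed; the default calibration selects 0.2 mS/cm².
- **Synapse**: one biexponential AMPAR event per trial,
  g(t) = g_peak·f·(e^(−t/τ_decay) − e^(−t/τ_rise)), τ_rise = 70 ms,
  τ_decay = 75 ms, E_syn = 0 mV, f normalizing the peak to g_peak.

**Spike threshold** of the model is defined as the separatrix: the peak
voltage of the trajectory driven 0.5% below rheobase. The empirical
max-d²V/dt² estimator (used in `ephys` on recorded-style traces) is *not*
used for the model because m³h kinetics initiate spikes gradually — the
second derivative peaks mid-upstroke, tens of mV above the dynamical
threshold. This is a known limitation of HH-style sodium kinetics relative
to the sharp initiation of real cortical spikes; the separatrix is the
quantity that actually governs clipping and distance-to-threshold.

**Group conditions** share every channel parameter and differ only
passively: `R_only` (g_L × 0.79), `Vrest_only` (E_L + 5 mV),
`food_restricted` (both). With these defaults the rheobase conductance of
the food-restricted model is ≈75% of control — emerging from, not imposed
on, the biophysics — consistent with the experimentally observed ≈30%
synaptic reduction.

**Noise models.**

- *External*: each trial's synaptic peak conductance is drawn from
  N(ḡ, σ) with σ = σ₀·ρ, ρ = ḡ/g₀(group); σ₀ (the SD at control rheobase)
  is calibrated so the control external-noise CV matches the control
  stochastic-channel CV (`calibrate_sigma0`, by local linearization of the
  noise-free response curve).
- *Stochastic channel*: only the slow Kv is stochastic. Its 5-state
  four-gate chain is advanced with fixed-step binomial transitions at
  dt = 0.01 ms; channel count N = ḡ_Ks·area/γ with single-channel
  conductance γ = 20 pS (N = 20 at the default calibration). The stationary
  open-count distribution is Binomial(N, n_∞⁴), verified against the
  integrator in the test suite.

**Variability measurement.** Per trial, action potentials are clipped at
threshold and the response is the 97.5th percentile of the remaining
samples after stimulus onset, minus rest. CV = sample SD / mean over
trials. Groups are compared at *matched normalized depolarization*: the
drive is set per group so the noise-free response reaches the same fraction
of the distance to threshold. The default fraction is 0.85 — the models
ride near threshold with occasional crossings, as in sample traces of such
simulations, while keeping the clipped response measure informative
(clipping begins to dominate, and eventually inverts, the CV above ≈0.9).
The 97.5th-percentile window is the whole post-onset trace (a config
choice; the stimulus-window-only variant gives indistinguishable values for
single-event trials).

**Input–output curves and tuning of spike probability.** P(≥1 spike) is
measured over a grid of rheobase fractions and fitted with a generalized
(Richards) logistic. Orientation sweeps map a Gaussian conductance tuning
curve (amplitude 0.9 of control rheobase, width 170°) through the fitted
curve; every group receives the same absolute conductance, so the group's
curve is evaluated at g·g₀(control)/g₀(group) in its own rheobase units.
The normalized spike-probability tuning is then fitted with a wrapped
Gaussian to report a width. Noisier groups have shallower input–output
curves, which preserves relative flank probability — hence broader tuning.

**Integrate-and-fire model.** Passive membrane with the same g_L, c_m and
rest as the HH model; a spike is counted when V reaches −40 mV. The
food-restricted variant imposes the experimental 30% synaptic reduction
(rheobase = 0.70 × control) together with g_L × 0.79 and E_L + 5 mV; its
normalized depolarization curve is compared with control over the 0–100%
rheobase grid.

**Numerics.** Exponential-Euler updates for all gates and the voltage
equation (V is relaxed toward the instantaneous quasi-steady-state with the
instantaneous total conductance — unconditionally stable). dt = 0.025 ms
for deterministic/external runs, 0.01 ms for stochastic runs; halving dt
changes peak voltages by <0.1 mV. Deterministic runs are bit-reproducible.
Rheobase is found by bisection to 0.1% relative precision; |V| > 200 mV
aborts with an integration-failure error. Only the calibrated HH-style Nav
backend is implemented; the `nav_backend` config field exists so an
alternative kinetic scheme can be added without interface changes.

## Trace analysis (`ephys`)

- **Spikes**: peaks above 0 mV with ≥20 mV prominence and ≥2 ms separation;
  per-spike threshold at max d²V/dt² within the preceding 5 ms. These
  findpeaks-style parameters are declared defaults, not fitted values.
- **Subthreshold extraction**: samples ≥ threshold become NaN; V_rest is
  the 5th percentile of unmasked samples in no-stimulus periods. Responses
  are median(grating) − median(preceding 1 s gray); the variability variant
  uses the 95th percentile of the grating window.
- **Intrinsic parameters**: each current-step relaxation is fitted with
  V(t) = V₀ + I·R_m(1−e^(−t/τ_m)) + I·R_a(1−e^(−t/τ_a)); the slower
  component is identified as the membrane; R_m and τ_m are averaged across
  steps and C_m = τ_m/R_m.
- **mEPSC detection**: template-free first pass on the smoothed derivative —
  onsets where the falling slope exceeds 4× a robust (MAD) SD — with an
  amplitude criterion (≥4× the robust baseline-current SD) and an isolation
  criterion (no neighboring event within the analysis window). Alignment
  uses the smoothed trace; raw-trace argmin alignment is biased toward
  noise minima and measurably inflates decay variance.
- **Mean–variance analysis**: template from ≥50 events with amplitudes
  >5 pA; each event minus its peak-scaled template over the decay phase
  (peak → 10% of peak); 30 equal fractional-amplitude bins; ensemble
  variance vs mean fitted with σ² = iμ − μ²/N + c. The unitary current i is
  the initial slope; conductance = i / 70 mV driving force (−70 mV holding,
  0 mV AMPAR reversal); N = mean amplitude / i. Events whose decay deviates
  from the scaled template by >9× the median mean-squared deviation are
  trimmed before the ensemble statistics: these are unresolved double
  events, whose inclusion dominates the variance and destroys the
  parabola. A clearly convex variance–mean relation raises an
  analysis-failure error with the fit diagnostics.
- Sample (n−1) SDs everywhere; trial counts in this kind of data are small.

## Energetics (`energetics`)

Synaptic: ATP/s = (net charge rate × 1.42 / e) / 3, where 1.42 corrects for
concurrent K+ efflux and 3 is the pump stoichiometry. Spiking: 1.35 × 10¹¹
ATP/spike/cm² × (C_m / 1 µF cm⁻²) × rate. Resting:
(V_Na−V_K)(V_rest−V_K)·A / (F·R·(V_rest−2V_Na−3V_K)) with V_Na = +50 mV,
V_K = −100 mV — dimensionally 1/s, enforced by evaluating in SI. Charge
rates are trapezoidal integrals divided by duration. Public interfaces use
the field's customary units (pA, pF, MΩ, mV) with SI conversions internal.

FRET decay: the YFP/CFP series is normalized by subtracting the mean of the
last 3 trials (plateau) and dividing by the resulting baseline mean,
clamped to [0,1]; the decay rate is the least-squares slope over the
interior points (first and last 3 excluded). A flat series yields 0 rather
than an error.

## Tuning (`tuning`)

ΔF/F uses F₀ = 5th percentile of the 1 Hz zero-phase 60th-order FIR
low-passed trace. Orientation fits are wrapped Gaussians with
ang_ori(x) = min(|x|,|x±180|) ≤ 90°; direction fits use two Gaussians of
shared width at θ_pref and θ_pref + 180° (ang_dir ≤ 180°). Constraints:
R_p ∈ [pref/2, pref] (pref = mean response at the empirically preferred
stimulus), R_n ∈ [0, pref], C fixed at 0 for ΔF/F data and free for
electrophysiological responses (both modes available); fits start from
σ ∈ {10°, 20°, 40°, 80°, 160°} and the lowest-SSE fit wins. The second
Gaussian is centered at the opposite direction — the natural reading of a
double (preferred/null) direction fit. BIC responsiveness compares the
offset-free double Gaussian (k = 4) against a flat-zero null (k = 0) over
all trial responses, with the mean residual SS floored at 10⁻¹² so perfect
fits stay finite; ΔBIC ≥ 10 declares responsiveness and holds the
false-positive rate on pure noise below 5%. Movie responsiveness floors
zero across-trial SDs at machine epsilon so deterministic positive
responses count as responsive (the limiting case of the ≥5 SD rule).

The Gaussian-noise spike model evaluates the normal *density* of the spike
threshold under N(μ(θ), cv·μ(θ)) — the literal reading — normalized to the
preferred orientation; a survival-function variant exists for sensitivity
analysis only. Width is monotone non-decreasing in cv for fixed μ.

## Decoding (`decoding`)

Leave-one-out ML: per held-out trial, per-neuron per-stimulus mean and
sample SD are estimated from the remaining trials (only the held-out
trial's own stimulus loses a trial); Gaussian log-likelihoods are summed
across neurons and the argmax stimulus taken. Zero SDs are floored at 10⁻⁶
of the population dynamic range; ties break uniformly at random under the
run seed. Neuron subsets (default 50) are drawn without replacement within
each of the default 100 resamples; subsets may overlap across resamples —
the only reading consistent with 100 draws from pools barely larger than
the subset. Accuracy is averaged per stimulus, then over stimuli and
resamples. Scene decoding is the same machinery with fine (exact bin,
chance 1/58) or coarse (same environment, chance 1/2) correctness rules.
Scene dissimilarity is the mean absolute 0–255 pixel difference over
designated scene pairs. Simulated orientation sets (spacings 5°–30°) draw
Gaussian responses from fitted tuning curves with σ(θ) = μ(θ) × pooled CV,
repeated (default 1000×) and averaged.

## Synthetic data (`synth`)

Generators are pure functions of (params, seed) and return their full
parameterization, so downstream estimands have closed forms. Choices worth
noting:

- Spontaneous membrane fluctuations are an Ornstein–Uhlenbeck process with
  20 ms correlation time — a standard in-vivo-like surrogate; the real
  gray-screen noise spectrum is not characterized, so this is a declared
  stand-in, not a claim about data.
- Inserted spikes are 1 ms triangular events to +20 mV: only threshold
  crossing and clipping behavior matter downstream.
- mEPSC decays are simulated mechanistically — all channels open at the
  peak, independent exponential closures — so instantaneous current is
  (open count) × unitary current and the mean–variance parabola is exact by
  construction.
- FRET series place the linear decay exactly across the interior trials
  (cadence derived from the rate), matching how such series are acquired:
  imaging continues until the plateau is visible.
- Default dt: 0.05 ms for voltage traces, 0.1 ms for current traces.

What the generators do **not** emulate: correlated noise across neurons,
non-Gaussian trial variability, calcium-indicator dynamics beyond the
response-window convention, neuropil contamination, motion artifacts, or
electrode drift. Passing tests therefore demonstrate estimator correctness
under the stated noise models, not robustness to every artifact of real
recordings.

## Known limitations

- The m³h Nav backend initiates spikes more gradually than real cortical
  neurons (and than allosteric Markov schemes). Consequences: the empirical
  d²V/dt² threshold does not mark the separatrix (handled by using the
  separatrix for model work), and near-threshold amplification of noise in
  the depolarized-rest condition is weaker than sharper Nav kinetics would
  produce — the depolarized-rest-only condition shows a smaller CV increase
  relative to the combined condition than sharp-initiation models yield.
- The external-noise CV ratios depend mildly on the matched-depolarization
  level; the default (0.85) is fixed and documented above.
- Stochastic-channel noise is *within-trial* (≈5 ms correlation time), so
  near threshold many trials graze the clipping level and the
  97.5th-percentile response statistic saturates; at the default matched
  level the group ordering of stochastic CVs is masked by this saturation
  (it is visible at lower drive, e.g. 0.75 of the distance to threshold).
  External (between-trial) noise does not suffer from this, because each
  trial's whole trajectory scales together.
- The integrate-and-fire compensation identity is exact only for a linear
  (current-based) synapse; with the conductance synapse and the stated
  voltages the divisive saturation term leaves a ~3% residual deviation
  between the compensated and control curves.
- The decoder assumes independent Gaussian responses per neuron; no
  noise-correlation modeling.
- The pipeline stages cover the package's own analyses; no readers for
  acquisition-system formats (ABF/WCP) are included.
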