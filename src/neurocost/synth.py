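"""Synthetic electrophysiology and imaging data with known ground truth.

Every generator is a pure function of its parameters and a seed, and returns
its full parameterization in a :class:`GroundTruth`, so each downstream
estimator can be validated against a closed-form estimand without any
recorded data. The generators emulate the study conditions of awake-mouse V1
recordings:

* current-clamp traces with orientation-tuned subthreshold depolarizations,
  trial-to-trial noise and stereotyped spikes;
* voltage-clamp traces with miniature EPSCs whose decays arise from a
  binomial channel model (independent channel closures);
* current-step responses with double-exponential relaxation (membrane +
  electrode components);
* neuron x stimulus x trial population response tensors with Gaussian
  orientation tuning and multiplicative trial noise;
* FRET ATP-sensor ratio series decaying after synthesis blockade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import PopulationResponses
from .energetics import FretSeries
from .tuning import ang_ori

__all__ = [
    "GroundTruth",
    "SyntheticRecording",
    "OrientationTuningSpec",
    "gen_vm_trace",
    "gen_mepsc_recording",
    "gen_step_response",
    "gen_population_responses",
    "gen_fret_series",
]

# Default sampling steps: 0.05 ms resolves spike d2V/dt2 in voltage traces,
# 0.1 ms resolves mEPSC rise in current traces.
DT_VM_MS = 0.05
DT_CURRENT_MS = 0.1

# Background subthreshold fluctuations are modeled as an Ornstein-Uhlenbeck
# process with a 20 ms correlation time — a standard surrogate for in-vivo-like
# synaptic bombardment; it is a declared stand-in, not a claim about data.
OU_TAU_MS = 20.0


@dataclass
class GroundTruth:
    """Full parameterization of a synthetic dataset."""

    true_params: dict
    seed: int


@dataclass
class SyntheticRecording:
    """A sampled trace (mV or pA) with stimulus windows and ground truth."""

    trace: np.ndarray
    dt_ms: float
    stimulus_windows: list[tuple[float, float, str]]
    truth: GroundTruth
    units: str = "mV"

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        dur = self.dt_ms * self.trace.size
        last = 0.0
        for start, stop, _ in self.stimulus_windows:
            if not (0 <= start < stop <= dur + 1e-9):
                raise ValueError("stimulus window outside trace duration")
            if start < last - 1e-9:
                raise ValueError("stimulus windows overlap")
            last = stop

    @property
    def duration_ms(self) -> float:
        return self.dt_ms * self.trace.size

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.trace.size) * self.dt_ms


@dataclass
class OrientationTuningSpec:
    """Gaussian orientation tuning of the mean subthreshold depolarization."""

    pref_deg: float = 0.0
    amp_mv: float = 10.0
    width_deg: float = 30.0
    baseline_mv: float = 0.0

    def mu(self, theta_deg):
        d = ang_ori(np.asarray(theta_deg, dtype=float) - self.pref_deg)
        return self.baseline_mv + self.amp_mv * np.exp(-(d**2) / (2 * self.width_deg**2))


def _ou(rng: np.random.Generator, n: int, dt_ms: float, sigma: float,
        tau_ms: float = OU_TAU_MS) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    if sigma == 0:
        return np.zeros(n)
    a = np.exp(-dt_ms / tau_ms)
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal()
    noise = sigma * np.sqrt(1 - a * a) * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i - 1]
    return x


def _spike_template(dt_ms: float, peak_mv: float = 20.0, width_ms: float = 1.0):
    """1 ms triangular spike waveform (only threshold crossing and clipping
    behavior matter downstream)."""
    n = max(3, int(round(width_ms / dt_ms)) | 1)
    half = n // 2
    up = np.linspace(0.0, 1.0, half + 1)
    return np.concatenate([up, up[-2::-1]]), half, peak_mv


def gen_vm_trace(
    tuning: OrientationTuningSpec,
    trial_cv: float,
    v_rest: float = -70.0,
    v_threshold: float = -42.0,
    n_trials: int = 8,
    seed: int = 0,
    orientations_deg=(0.0, 30.0, 60.0, 90.0, 120.0, 150.0),
    dt_ms: float = DT_VM_MS,
    gray_ms: float = 1000.0,
    stim_ms: float = 2000.0,
    ou_sigma_mv: float = 0.3,
) -> SyntheticRecording:
    """Synthetic current-clamp trace with tuned, noisy grating responses.

    Each trial is ``gray_ms`` of gray screen followed by ``stim_ms`` of one
    grating orientation. The per-trial depolarization is drawn from
    Normal(mu(theta), trial_cv * mu(theta)) and rides on a stationary OU
    background; whenever the membrane potential crosses ``v_threshold`` a
    stereotyped triangular spike is inserted (2 ms refractoriness) and its
    time recorded in the truth.
    """
    if trial_cv < 0:
        raise ValueError("trial_cv must be non-negative")
    if v_threshold <= v_rest:
        raise ValueError("v_threshold must exceed v_rest")
    rng = np.random.default_rng(seed)
    n_gray = int(round(gray_ms / dt_ms))
    n_stim = int(round(stim_ms / dt_ms))
    n_per = n_gray + n_stim
    orientations = list(orientations_deg)
    total = n_per * n_trials * len(orientations)

    # smooth 20 ms raised-cosine onset/offset for the stimulus envelope
    n_edge = max(1, int(round(20.0 / dt_ms)))
    envelope = np.zeros(n_per)
    envelope[n_gray:] = 1.0
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_edge)))
    envelope[n_gray : n_gray + n_edge] = ramp
    envelope[-n_edge:] *= ramp[::-1]

    trace = np.empty(total)
    windows: list[tuple[float, float, str]] = []
    depols: list[float] = []
    trial_thetas: list[float] = []
    spike_times: list[float] = []
    pos = 0
    for trial in range(n_trials):
        for theta in orientations:
            mu = float(tuning.mu(theta))
            depol = rng.normal(mu, trial_cv * abs(mu)) if trial_cv > 0 else mu
            seg = v_rest + depol * envelope + _ou(rng, n_per, dt_ms, ou_sigma_mv)
            # insert stereotyped spikes at threshold crossings
            tmpl, half, peak = _spike_template(dt_ms)
            above = seg >= v_threshold
            i = 1
            while i < n_per:
                if above[i] and not above[i - 1]:
                    lo = max(0, i - half)
                    hi = min(n_per, i + half + 1)
                    shape = tmpl[half - (i - lo) : half + (hi - i)]
                    seg[lo:hi] = np.maximum(seg[lo:hi], seg[i] + (peak - seg[i]) * shape)
                    spike_times.append((pos + i) * dt_ms)
                    i += int(round(2.0 / dt_ms))  # refractory skip
                else:
                    i += 1
            trace[pos : pos + n_per] = seg
            t0 = pos * dt_ms
            windows.append((t0 + gray_ms, t0 + gray_ms + stim_ms, f"ori:{theta:g}"))
            depols.append(depol)
            trial_thetas.append(theta)
            pos += n_per

    truth = GroundTruth(
        true_params={
            "tuning": tuning,
            "trial_cv": trial_cv,
            "v_rest": v_rest,
            "v_threshold": v_threshold,
            "depolarizations_mv": np.array(depols),
            "trial_orientations_deg": np.array(trial_thetas),
            "spike_times_ms": np.array(spike_times),
            "ou_sigma_mv": ou_sigma_mv,
            "gray_ms": gray_ms,
            "stim_ms": stim_ms,
        },
        seed=seed,
    )
    return SyntheticRecording(trace, dt_ms, windows, truth, units="mV")


def gen_mepsc_recording(
    n_channels: int,
    unitary_current_pa: float,
    event_rate_hz: float,
    duration_s: float,
    baseline_noise_sd_pa: float = 0.5,
    seed: int = 0,
    tau_decay_ms: float = 5.0,
    rise_ms: float = 0.5,
    dt_ms: float = DT_CURRENT_MS,
) -> SyntheticRecording:
    """Synthetic voltage-clamp trace with binomial-channel mEPSCs.

    Events occur at Poisson times. At each event peak all ``n_channels``
    AMPAR channels are open; each then closes independently after an
    exponential lifetime (mean ``tau_decay_ms``), so the instantaneous event
    current is (open count) x unitary current — the binomial statistics that
    mean-variance analysis inverts. Currents are negative-going (inward at a
    -70 mV holding potential).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if unitary_current_pa <= 0:
        raise ValueError("unitary_current must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * 1000.0 / dt_ms))
    trace = np.zeros(n)
    n_events = rng.poisson(event_rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0, duration_s * 1000.0, size=n_events))
    n_rise = max(1, int(round(rise_ms / dt_ms)))
    n_decay = int(round(8.0 * tau_decay_ms / dt_ms))
    rise_shape = np.linspace(1.0 / n_rise, 1.0, n_rise)
    t_decay = np.arange(1, n_decay + 1) * dt_ms
    for t0 in onsets:
        i0 = int(round(t0 / dt_ms))
        if i0 >= n:
            continue
        lifetimes = rng.exponential(tau_decay_ms, size=n_channels)
        open_count = (lifetimes[None, :] > t_decay[:, None]).sum(axis=1)
        event = np.concatenate([rise_shape * n_channels, open_count.astype(float)])
        hi = min(n, i0 + event.size)
        trace[i0:hi] += -unitary_current_pa * event[: hi - i0]
    if baseline_noise_sd_pa > 0:
        trace += rng.normal(0.0, baseline_noise_sd_pa, size=n)
    truth = GroundTruth(
        true_params={
            "n_channels": n_channels,
            "unitary_current_pa": unitary_current_pa,
            "event_rate_hz": event_rate_hz,
            "event_times_ms": onsets,
            "tau_decay_ms": tau_decay_ms,
            "baseline_noise_sd_pa": baseline_noise_sd_pa,
        },
        seed=seed,
    )
    return SyntheticRecording(trace, dt_ms, [], truth, units="pA")


def gen_step_response(
    r_m_mohm: float,
    c_m_pf: float,
    r_a_mohm: float = 10.0,
    tau_a_ms: float = 0.5,
    current_steps_pa=(-200.0, -150.0, -100.0, -50.0, 50.0, 100.0, 150.0, 200.0),
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    v0_mv: float = -70.0,
    step_ms: float = 500.0,
    gap_ms: float = 200.0,
    dt_ms: float = DT_VM_MS,
) -> SyntheticRecording:
    """Current-step voltage relaxations with double-exponential kinetics.

    Each step's relaxation follows V(t) = V0 + I*(Rm(1 - e^{-t/tau_m}) +
    Ra(1 - e^{-t/tau_a})) with tau_m = Rm * Cm — the membrane component plus
    a fast electrode (access) component. Steps are concatenated with
    baseline gaps and labeled windows.
    """
    steps = list(current_steps_pa)
    if not steps:
        raise ValueError("need at least one current step")
    if r_m_mohm <= 0 or c_m_pf <= 0:
        raise ValueError("r_m and c_m must be positive")
    rng = np.random.default_rng(seed)
    tau_m_ms = r_m_mohm * c_m_pf * 1e-3  # MOhm * pF = us
    n_step = int(round(step_ms / dt_ms))
    n_gap = int(round(gap_ms / dt_ms))
    t = np.arange(n_step) * dt_ms
    segs, windows = [], []
    pos_ms = 0.0
    for i_pa in steps:
        # pA * MOhm = uV; convert to mV
        dv = i_pa * 1e-3 * (
            r_m_mohm * (1 - np.exp(-t / tau_m_ms))
            + r_a_mohm * (1 - np.exp(-t / tau_a_ms))
        )
        segs.append(np.full(n_gap, v0_mv))
        segs.append(v0_mv + dv)
        windows.append((pos_ms + gap_ms, pos_ms + gap_ms + step_ms, f"step:{i_pa:g}pA"))
        pos_ms += gap_ms + step_ms
    trace = np.concatenate(segs)
    if noise_sd_mv > 0:
        trace = trace + rng.normal(0.0, noise_sd_mv, size=trace.size)
    truth = GroundTruth(
        true_params={
            "r_m_mohm": r_m_mohm,
            "c_m_pf": c_m_pf,
            "tau_m_ms": tau_m_ms,
            "r_a_mohm": r_a_mohm,
            "tau_a_ms": tau_a_ms,
            "steps_pa": np.array(steps),
            "noise_sd_mv": noise_sd_mv,
            "v0_mv": v0_mv,
        },
        seed=seed,
    )
    return SyntheticRecording(trace, dt_ms, windows, truth, units="mV")


def gen_population_responses(
    n_neurons: int,
    stimuli,
    tuning_width_deg: float = 30.0,
    response_cv: float = 0.3,
    n_trials: int = 10,
    seed: int = 0,
    amp_lognorm_sigma: float = 0.5,
    baseline_frac: float = 0.05,
) -> PopulationResponses:
    """Population response tensor with Gaussian tuning and trial noise.

    ``stimuli`` is either a sequence of orientations in degrees (tuning uses
    the wrapped 180-degree metric) or arbitrary scene labels (tuning uses
    index distance, in label steps). Each neuron draws a random preferred
    stimulus and a lognormal response amplitude; trial responses are
    Normal(mu, response_cv * mu). A small positive baseline keeps mu > 0 so
    the multiplicative noise model is well defined everywhere.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    if response_cv < 0:
        raise ValueError("response_cv must be non-negative")
    rng = np.random.default_rng(seed)
    labels = list(stimuli)
    n_stim = len(labels)
    numeric = all(isinstance(s, (int, float, np.floating, np.integer)) for s in labels)
    if numeric:
        th = np.asarray(labels, dtype=float)
        pref = rng.uniform(0.0, 180.0, size=n_neurons)
        dist = ang_ori(th[None, :] - pref[:, None])
        width = tuning_width_deg
    else:
        idx = np.arange(n_stim, dtype=float)
        pref = rng.uniform(0, n_stim, size=n_neurons)
        raw = np.abs(idx[None, :] - pref[:, None])
        dist = np.minimum(raw, n_stim - raw)
        width = max(tuning_width_deg * n_stim / 180.0, 1.0)
    amp = rng.lognormal(mean=0.0, sigma=amp_lognorm_sigma, size=n_neurons)
    if np.isinf(width):
        mu = amp[:, None] * np.ones((n_neurons, n_stim))
    else:
        mu = amp[:, None] * (
            baseline_frac + (1 - baseline_frac) * np.exp(-(dist**2) / (2 * width**2))
        )
    x = np.repeat(mu[:, :, None], n_trials, axis=2)
    if response_cv > 0:
        x = rng.normal(x, response_cv * x)
    truth = {
        "pref": pref,
        "amp": amp,
        "mu": mu,
        "tuning_width_deg": tuning_width_deg,
        "response_cv": response_cv,
        "seed": seed,
    }
    return PopulationResponses(x, labels=labels, truth=truth)


def gen_fret_series(
    decay_rate_per_s: float,
    n_trials: int = 14,
    noise_sd: float = 0.0,
    seed: int = 0,
    trial_duration_s: float | None = None,
) -> FretSeries:
    """FRET ATP-sensor ratio series: baseline, linear decay, plateau.

    The normalized signal sits at 1.0 for the first 3 trials, decays
    linearly at ``decay_rate_per_s`` (non-positive, in normalized units per
    second), and plateaus at 0 for the last 3 trials, with additive Gaussian
    noise. By default the trial cadence is chosen so the decay spans exactly
    the interior trials (from trial 3 to trial ``n_trials - 3``), matching
    how such series are acquired: imaging is continued until the sensor
    signal has visibly plateaued. At least 7 trials are required so the
    downstream estimator can drop the first and last 3 points.
    """
    if decay_rate_per_s > 0:
        raise ValueError("decay_rate must be <= 0 (signal decays)")
    if n_trials < 7:
        raise ValueError("need at least 7 trials")
    rng = np.random.default_rng(seed)
    if trial_duration_s is None:
        if decay_rate_per_s < 0:
            # full decay (1 -> 0) over the (n_trials - 6) interior intervals
            trial_duration_s = -1.0 / (decay_rate_per_s * (n_trials - 6))
        else:
            trial_duration_s = 2.0
    t = np.arange(n_trials, dtype=float) * trial_duration_s
    t0 = 3 * trial_duration_s
    values = np.clip(1.0 + decay_rate_per_s * np.clip(t - t0, 0.0, None), 0.0, 1.0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_trials)
    truth = {
        "decay_rate_per_s": decay_rate_per_s,
        "noise_sd": noise_sd,
        "trial_duration_s": trial_duration_s,
        "seed": seed,
    }
    return FretSeries(values, trial_duration_s, drug_onset_index=3, truth=truth)
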