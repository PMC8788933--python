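"""ATP budgets from electrophysiology and FRET-sensor decay analysis.

Cortical signaling costs are dominated by the Na+/K+-ATPase reversing the
Na+ influx of synaptic currents, action potentials and the resting leak.
This module converts standard electrophysiological measurements (charge
transfer rates, spike rates, input resistance, resting potential) into ATP
consumption rates, and estimates relative ATP usage from the decay of a
ratiometric FRET ATP sensor after blockade of ATP synthesis.

Unit conventions follow the formulas' original mixed units (pA, MOhm, mV,
uF) at the public surface, with SI conversions internal to each function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyConstants",
    "CONSTANTS",
    "FretSeries",
    "charge_transfer_rate",
    "atp_rate_synaptic",
    "atp_rate_spiking",
    "atp_rate_resting",
    "fret_decay_rate",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Physical constants and cost conventions used by the ATP calculators.

    ``na_correction`` accounts for the fact that the inward charge carried by
    excitatory currents comprises 1.42x more Na+ than the net charge, owing to
    concurrent K+ efflux. ``na_per_atp`` is the pump stoichiometry (3 Na+
    extruded per ATP). ``atp_per_spike_per_cm2`` is the per-spike somatic cost
    for a regular-spiking rodent cortical neuron, per unit membrane area.
    """

    na_correction: float = 1.42
    na_per_atp: float = 3.0
    atp_per_spike_per_cm2: float = 1.35e11
    specific_capacitance_uf_cm2: float = 1.0
    v_na_mv: float = 50.0
    v_k_mv: float = -100.0
    avogadro: float = 6.02214076e23
    faraday: float = 96485.33212
    elementary_charge: float = 1.602176634e-19


CONSTANTS = EnergyConstants()


@dataclass
class FretSeries:
    """Per-trial YFP/CFP FRET ratio values from an ATP sensor.

    ``values`` holds one ratio per imaging trial; ``trial_duration_s`` is the
    time between consecutive trials; ``drug_onset_index`` marks the first trial
    after ATP-synthesis blockade (decay begins there). ``truth`` carries the
    generating parameters when the series is synthetic.
    """

    values: np.ndarray
    trial_duration_s: float
    drug_onset_index: int = 3
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")


def charge_transfer_rate(current_pa: np.ndarray, dt_ms: float) -> float:
    """Mean rate of charge transfer of a current trace, in pA.

    The trace is integrated (trapezoid rule) and divided by its duration, so
    the result is simply the time-averaged current. Exposed separately so the
    synaptic ATP calculator can be composed with raw voltage-clamp traces.
    """
    current_pa = np.asarray(current_pa, dtype=float)
    if current_pa.ndim != 1 or current_pa.size < 2:
        raise ValueError("need a 1-D trace with at least two samples")
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    duration = dt_ms * (current_pa.size - 1)
    return float(np.trapezoid(current_pa, dx=dt_ms) / duration)


def atp_rate_synaptic(
    stim_charge_rate_pa: float,
    baseline_charge_rate_pa: float,
    constants: EnergyConstants = CONSTANTS,
) -> float:
    """ATP/s to reverse the Na+ influx of stimulus-evoked synaptic current.

    The baseline (gray screen) charge-transfer rate is subtracted from the
    stimulus rate; the net rate is scaled by 1.42 to obtain the Na+ influx
    rate and divided by 3 (Na+ per ATP). A net outward current yields a
    negative value; callers may treat that as a quality flag.
    """
    net_pa = stim_charge_rate_pa - baseline_charge_rate_pa
    charges_per_s = net_pa * 1e-12 / constants.elementary_charge
    return charges_per_s * constants.na_correction / constants.na_per_atp


def atp_rate_spiking(
    spike_rate_hz: float,
    capacitance_pf: float,
    constants: EnergyConstants = CONSTANTS,
) -> float:
    """ATP/s consumed by somatic action potentials.

    ``capacitance_pf`` (whole-cell) divided by the specific capacitance
    (1 uF/cm^2) gives the membrane area; the per-spike, per-area cost is then
    scaled by the baseline-subtracted spike rate.
    """
    if capacitance_pf < 0:
        raise ValueError("capacitance must be non-negative")
    capacitance_uf = capacitance_pf * 1e-6
    area_cm2 = capacitance_uf / constants.specific_capacitance_uf_cm2
    return constants.atp_per_spike_per_cm2 * area_cm2 * spike_rate_hz


def atp_rate_resting(
    input_resistance_mohm: float,
    v_rest_mv: float,
    constants: EnergyConstants = CONSTANTS,
) -> float:
    """ATP/s spent holding the resting potential.

    Evaluates, in SI units,

        ATP/s = (V_Na - V_K)(V_rest - V_K) * A / (F * R * (V_rest - 2 V_Na - 3 V_K))

    which follows from the steady-state balance of Na+ and K+ leak currents at
    rest and the 3:2 pump stoichiometry. Dimensions: V^2 * mol^-1 /
    ((C/mol) * Ohm * V) = A / C = 1/s.
    """
    if input_resistance_mohm <= 0:
        raise ValueError("input resistance must be positive")
    v_na = constants.v_na_mv * 1e-3
    v_k = constants.v_k_mv * 1e-3
    v_rest = v_rest_mv * 1e-3
    if not (v_k < v_rest < v_na):
        raise ValueError("v_rest must lie between V_K and V_Na")
    r_ohm = input_resistance_mohm * 1e6
    denom_v = v_rest - 2.0 * v_na - 3.0 * v_k
    if denom_v == 0:
        raise ZeroDivisionError("singular input: V_rest - 2V_Na - 3V_K = 0")
    return (
        (v_na - v_k)
        * (v_rest - v_k)
        * constants.avogadro
        / (constants.faraday * r_ohm * denom_v)
    )


def normalize_fret(series: FretSeries) -> np.ndarray:
    """Bound a FRET series to [0, 1].

    Subtracts the mean of the last 3 trials (the post-blockade plateau), then
    divides by the mean of the resulting baseline (first 3 trials), clamping
    to [0, 1].
    """
    x = series.values
    if x.size < 7:
        raise ValueError("need at least 7 trials (3 baseline + interior + 3 plateau)")
    y = x - x[-3:].mean()
    base = y[:3].mean()
    if base <= 1e-9 * max(1.0, np.abs(x).max()):
        # flat series: baseline equals plateau, nothing decayed
        return np.zeros_like(y)
    return np.clip(y / base, 0.0, 1.0)


def fret_decay_rate(series: FretSeries) -> float:
    """Decay rate (per second) of a normalized FRET ATP-sensor series.

    The slope of a least-squares linear fit over the interior points of the
    normalized series — the first 3 (baseline) and last 3 (plateau) points are
    excluded. Negative for a decaying signal; more negative means faster ATP
    consumption.
    """
    y = normalize_fret(series)
    t = np.arange(y.size) * series.trial_duration_s
    ti, yi = t[3:-3], y[3:-3]
    if ti.size < 2:
        raise ValueError("insufficient interior points for a linear fit")
    slope, _ = np.polyfit(ti, yi, 1)
    return float(slope)
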