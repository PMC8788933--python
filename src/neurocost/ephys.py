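"""Analysis of current-clamp and voltage-clamp recordings.

Spike detection and threshold estimation, subthreshold extraction (spike
clipping), grating-evoked response and trial-to-trial variability measures,
passive intrinsic parameters from current steps, mEPSC detection, binomial
mean-variance (nonstationary fluctuation) analysis of mEPSC decays, paired-
pulse and 1/CV^2 synaptic measures, and in vivo input-output curves.

Voltage conventions: mV and ms everywhere; currents in pA. Sample (n-1
denominator) standard deviations are used throughout — trial counts are
small in this kind of data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .synth import SyntheticRecording

__all__ = [
    "SpikeTrain",
    "SubthresholdTrace",
    "IntrinsicParams",
    "MEPSCSet",
    "MeanVarianceResult",
    "detect_spikes",
    "extract_subthreshold",
    "grating_response_vm",
    "trial_cv",
    "fit_intrinsic_params",
    "detect_mepscs",
    "mean_variance_analysis",
    "paired_pulse_ratio",
    "inv_cv2",
    "io_curve_invivo",
]

# findpeaks-style defaults: the acquisition tool's parameters are not part of
# the analysis definition, so these are declared here, not inferred.
SPIKE_MIN_HEIGHT_MV = 0.0
SPIKE_MIN_PROMINENCE_MV = 20.0
SPIKE_MIN_SEPARATION_MS = 2.0
THRESHOLD_LOOKBACK_MS = 5.0


@dataclass
class SpikeTrain:
    spike_times_ms: np.ndarray
    thresholds_mv: np.ndarray

    @property
    def mean_threshold_mv(self) -> float:
        if self.thresholds_mv.size == 0:
            return float("nan")
        return float(self.thresholds_mv.mean())

    def __len__(self) -> int:
        return self.spike_times_ms.size


@dataclass
class SubthresholdTrace:
    """Voltage trace with super-threshold samples replaced by NaN."""

    samples: np.ndarray
    dt_ms: float
    v_rest_mv: float
    masked_fraction: float
    quality_warning: bool = False


@dataclass
class IntrinsicParams:
    r_m_mohm: float
    tau_m_ms: float
    c_m_pf: float
    r_a_mohm: float
    tau_a_ms: float

    def __post_init__(self) -> None:
        # C_m = tau_m / R_m by definition; enforce consistency
        self.c_m_pf = self.tau_m_ms / self.r_m_mohm * 1e3


@dataclass
class MEPSCSet:
    """Aligned miniature-EPSC waveforms (positive-amplitude convention)."""

    waveforms: np.ndarray  # (n_events, n_samples), peak at `peak_index`
    dt_ms: float
    peak_index: int
    amplitudes_pa: np.ndarray
    frequency_hz: float


@dataclass
class MeanVarianceResult:
    bin_means_pa: np.ndarray
    bin_variances_pa2: np.ndarray
    unitary_current_pa: float
    single_channel_conductance_ps: float
    open_channel_number: float
    fit_coeffs: np.ndarray


def detect_spikes(trace: np.ndarray, dt_ms: float) -> SpikeTrain:
    """Detect action potentials and estimate per-spike thresholds.

    Peaks above 0 mV with at least 20 mV prominence and 2 ms separation are
    taken as spikes. The threshold of each spike is the voltage at the point
    maximizing d2V/dt2 in the 5 ms preceding the peak.
    """
    v = np.asarray(trace, dtype=float)
    if dt_ms > 0.1:
        raise ValueError("spike detection requires dt <= 0.1 ms")
    distance = max(1, int(round(SPIKE_MIN_SEPARATION_MS / dt_ms)))
    peaks, _ = signal.find_peaks(
        v,
        height=SPIKE_MIN_HEIGHT_MV,
        prominence=SPIKE_MIN_PROMINENCE_MV,
        distance=distance,
    )
    lookback = max(2, int(round(THRESHOLD_LOOKBACK_MS / dt_ms)))
    thresholds = np.empty(peaks.size)
    for k, p in enumerate(peaks):
        lo = max(0, p - lookback)
        seg = v[lo : p + 1]
        d2 = np.gradient(np.gradient(seg, dt_ms), dt_ms)
        thresholds[k] = seg[int(np.argmax(d2))]
    return SpikeTrain(peaks * dt_ms, thresholds)


def extract_subthreshold(
    rec_or_trace,
    threshold_mv: float,
    dt_ms: float | None = None,
    gray_mask: np.ndarray | None = None,
) -> SubthresholdTrace:
    """Mask super-threshold samples and estimate the resting potential.

    Samples at or above ``threshold_mv`` become NaN (spike clipping). V_rest
    is the 5th percentile of the remaining samples, restricted to
    ``gray_mask`` (no-stimulus periods) when provided. A quality warning is
    raised when more than half the samples are masked.
    """
    if isinstance(rec_or_trace, SyntheticRecording):
        v = rec_or_trace.trace.copy()
        dt_ms = rec_or_trace.dt_ms
        if gray_mask is None:
            gray_mask = np.ones(v.size, dtype=bool)
            for start, stop, _ in rec_or_trace.stimulus_windows:
                i0, i1 = int(start / dt_ms), int(stop / dt_ms)
                gray_mask[i0:i1] = False
    else:
        v = np.asarray(rec_or_trace, dtype=float).copy()
        if dt_ms is None:
            raise ValueError("dt_ms required for a bare trace")
    mask = v >= threshold_mv
    v[mask] = np.nan
    frac = float(mask.mean())
    pool = v if gray_mask is None else v[gray_mask]
    pool = pool[np.isfinite(pool)]
    v_rest = float(np.percentile(pool, 5)) if pool.size else float("nan")
    return SubthresholdTrace(v, dt_ms, v_rest, frac, quality_warning=frac > 0.5)


def grating_response_vm(
    sub: SubthresholdTrace,
    window_ms: tuple[float, float],
    baseline_ms: float = 1000.0,
    percentile: float | None = None,
) -> float:
    """Stimulus-evoked subthreshold depolarization for one grating trial.

    Median membrane potential during the grating window minus the median in
    the preceding gray period (``baseline_ms`` long). Passing
    ``percentile=95`` switches the stimulus statistic to the 95th percentile,
    the variant used when quantifying trial-to-trial variability (it captures
    large within-trial deviations).
    """
    start, stop = window_ms
    n = sub.samples.size
    i0, i1 = int(round(start / sub.dt_ms)), int(round(stop / sub.dt_ms))
    ib = i0 - int(round(baseline_ms / sub.dt_ms))
    if ib < 0 or i1 > n or i0 >= i1:
        raise IndexError("stimulus/baseline window outside trace")
    stim = sub.samples[i0:i1]
    gray = sub.samples[ib:i0]
    stat = (
        np.nanmedian(stim)
        if percentile is None
        else np.nanpercentile(stim, percentile)
    )
    return float(stat - np.nanmedian(gray))


def trial_cv(responses) -> float:
    """Coefficient of variation (sample SD / mean) of per-trial responses."""
    r = np.asarray(responses, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 trials")
    mean = r.mean()
    if mean <= 0:
        raise ValueError("undefined CV: mean response <= 0")
    return float(r.std(ddof=1) / mean)


def _double_exp_rise(t, v0, a_m, tau_m, a_a, tau_a):
    return v0 + a_m * (1 - np.exp(-t / tau_m)) + a_a * (1 - np.exp(-t / tau_a))


def fit_intrinsic_params(steps: SyntheticRecording) -> IntrinsicParams:
    """Passive membrane parameters from current-step relaxations.

    Each step's voltage relaxation is fit to the double exponential
    V(t) = V0 + Rm*I*(1 - e^{-t/tau_m}) + Ra*I*(1 - e^{-t/tau_a}), separating
    the membrane from the faster electrode (access) component; Rm and tau_m
    are averaged across steps and C_m = tau_m / Rm. Step amplitudes are read
    from the window labels (``step:<amp>pA``).
    """
    rms, taums, ras, tauas = [], [], [], []
    n_fail = 0
    dt = steps.dt_ms
    for start, stop, label in steps.stimulus_windows:
        if not label.startswith("step:"):
            continue
        i_pa = float(label[5:].rstrip("pA"))
        i0, i1 = int(round(start / dt)), int(round(stop / dt))
        seg = steps.trace[i0:i1]
        t = np.arange(seg.size) * dt
        dv_end = seg[-1] - seg[0]
        p0 = (seg[0], 0.9 * dv_end, 10.0, 0.1 * dv_end, 0.5)
        try:
            popt, _ = optimize.curve_fit(
                _double_exp_rise, t, seg, p0=p0, maxfev=20000
            )
        except RuntimeError:
            n_fail += 1
            continue
        _, a_m, tau_m, a_a, tau_a = popt
        if tau_m < tau_a:  # identify the slower component as the membrane
            a_m, tau_m, a_a, tau_a = a_a, tau_a, a_m, tau_m
        rms.append(a_m / (i_pa * 1e-3))  # mV / pA = MOhm * 1e... -> a_m[mV]/I[pA]*1e3
        taums.append(tau_m)
        ras.append(a_a / (i_pa * 1e-3))
        tauas.append(tau_a)
    n_total = n_fail + len(rms)
    if n_total == 0:
        raise ValueError("no current-step windows found")
    if n_fail > 0.5 * n_total:
        raise RuntimeError("fit failure on more than half of the steps")
    r_m = float(np.mean(rms))
    tau_m = float(np.mean(taums))
    return IntrinsicParams(
        r_m_mohm=r_m,
        tau_m_ms=tau_m,
        c_m_pf=tau_m / r_m * 1e3,
        r_a_mohm=float(np.mean(ras)),
        tau_a_ms=float(np.mean(tauas)),
    )


def detect_mepscs(
    rec: SyntheticRecording,
    detection_sd: float = 4.0,
    pre_ms: float = 5.0,
    post_ms: float = 40.0,
    min_separation_ms: float = 5.0,
) -> MEPSCSet:
    """Detect miniature EPSCs in a voltage-clamp current trace.

    Template-free first pass: the trace is lightly smoothed and negative-
    going peaks exceeding ``detection_sd`` times a robust (MAD-based)
    baseline SD are taken as events. Each event is windowed (``pre_ms``
    before to ``post_ms`` after the peak), its amplitude measured baseline-
    to-peak, and stored in positive-amplitude convention.
    """
    i_trace = rec.trace
    dt = rec.dt_ms
    n_smooth = max(1, int(round(0.5 / dt)))
    kernel = np.ones(n_smooth) / n_smooth
    smooth = np.convolve(i_trace, kernel, mode="same")
    # onset detection on the falling slope: the fast rise of an inward event
    # gives a large negative derivative, while the slow, stepwise decay does
    # not — this separates event onsets from decay fluctuations
    fall = -np.diff(smooth)
    sd = 1.4826 * np.median(np.abs(fall - np.median(fall)))
    height = np.median(fall) + detection_sd * max(sd, 1e-12)
    distance = max(1, int(round(min_separation_ms / dt)))
    onsets, _ = signal.find_peaks(fall, height=height, distance=distance)
    n_pre = int(round(pre_ms / dt))
    n_post = int(round(post_ms / dt))
    n_search = max(2, 4 * n_smooth)
    # amplitude criterion: events must also exceed detection_sd x the robust
    # baseline-current SD, suppressing slope-trigger false positives
    sd_current = 1.4826 * np.median(np.abs(i_trace - np.median(i_trace)))
    min_amp = detection_sd * max(sd_current, 1e-12)
    waveforms, amps = [], []
    n_detected = 0
    for k, o in enumerate(onsets):
        hi = min(i_trace.size, o + n_search)
        # align on the smoothed trace: raw-trace argmin is biased toward
        # noise minima, jittering alignment and inflating decay variance
        p_raw = o + int(np.argmin(smooth[o:hi]))
        lo_base = max(0, p_raw - n_pre)
        base = np.median(-i_trace[lo_base : max(lo_base + 1, p_raw - n_pre // 2)])
        amp = -i_trace[p_raw] - base
        if amp < min_amp:
            continue
        n_detected += 1  # frequency counts every event, overlapping or not
        if p_raw - n_pre < 0 or p_raw + n_post >= i_trace.size:
            continue
        # isolation: discard events whose analysis window overlaps a
        # neighbor — only well-defined, uncontaminated decays are kept
        if k > 0 and (o - onsets[k - 1]) * dt < pre_ms + post_ms:
            continue
        if k + 1 < onsets.size and (onsets[k + 1] - o) * dt < post_ms:
            continue
        w = -i_trace[p_raw - n_pre : p_raw + n_post]
        base = np.median(w[: max(1, n_pre // 2)])
        waveforms.append(w - base)
        amps.append(w[n_pre] - base)
    waveforms = np.array(waveforms) if waveforms else np.empty((0, n_pre + n_post))
    duration_s = rec.duration_ms / 1000.0
    return MEPSCSet(
        waveforms=waveforms,
        dt_ms=dt,
        peak_index=n_pre,
        amplitudes_pa=np.asarray(amps, dtype=float),
        frequency_hz=n_detected / duration_s,
    )


def mean_variance_analysis(
    events: MEPSCSet,
    driving_force_mv: float = 70.0,
    n_bins: int = 30,
    min_amplitude_pa: float = 5.0,
    min_events: int = 50,
    decay_floor: float = 0.1,
) -> MeanVarianceResult:
    """Binomial mean-variance (nonstationary fluctuation) analysis of mEPSCs.

    A template is built from at least ``min_events`` well-defined events
    (amplitude > ``min_amplitude_pa``). Each event is compared with the
    peak-scaled template over the decay phase (template peak down to
    ``decay_floor`` of peak); the decay is divided into ``n_bins`` equal
    fractional-amplitude bins and, per bin, the ensemble mean current and the
    ensemble variance of the event-minus-scaled-template differences are
    computed. Under binomial channel statistics the variance-mean relation is
    the parabola

        var = i * mu - mu^2 / N

    so the initial slope estimates the unitary current i; dividing by the
    driving force gives the open-channel conductance, and the mean event
    amplitude divided by i gives the mean open channel number N.
    """
    sel = events.amplitudes_pa > min_amplitude_pa
    if sel.sum() < min_events:
        raise ValueError(
            f"need at least {min_events} events above {min_amplitude_pa} pA"
        )
    w = events.waveforms[sel]
    amps = events.amplitudes_pa[sel]
    template = w.mean(axis=0)
    p = events.peak_index
    tmpl_peak = template[p]
    decay = template[p:]
    # decay phase: peak down to decay_floor of peak
    below = np.flatnonzero(decay <= decay_floor * tmpl_peak)
    end = below[0] if below.size else decay.size
    if end < n_bins:
        raise ValueError("decay phase too short for the requested bin count")
    frac = decay[:end] / tmpl_peak  # fractional amplitude, 1 -> decay_floor
    edges = np.linspace(1.0, decay_floor, n_bins + 1)
    bin_idx = np.clip(np.digitize(-frac, -edges[1:]), 0, n_bins - 1)
    scale = amps / tmpl_peak
    ev_decay = w[:, p : p + end]
    diffs = ev_decay - scale[:, None] * decay[None, :end]
    # template-match rejection: unresolved double events (a second release
    # riding on the decay) deviate grossly from the scaled template and
    # would dominate the ensemble variance; trim them and rebuild
    msd = (diffs**2).mean(axis=1)
    keep = msd <= 9.0 * max(np.median(msd), 1e-30)
    if keep.sum() >= min_events and not keep.all():
        w, amps = w[keep], amps[keep]
        template = w.mean(axis=0)
        tmpl_peak = template[p]
        decay = template[p:]
        scale = amps / tmpl_peak
        ev_decay = w[:, p : p + end]
        diffs = ev_decay - scale[:, None] * decay[None, :end]
    means = np.empty(n_bins)
    variances = np.empty(n_bins)
    for b in range(n_bins):
        cols = bin_idx == b
        if not cols.any():
            means[b] = np.nan
            variances[b] = np.nan
            continue
        means[b] = ev_decay[:, cols].mean()
        variances[b] = diffs[:, cols].mean(axis=1).var(ddof=1)
    ok = np.isfinite(means)
    coeffs = np.polyfit(means[ok], variances[ok], 2)  # a*mu^2 + b*mu + c
    a, b, _ = coeffs
    var_span = float(np.nanmax(variances) - np.nanmin(variances))
    if var_span > 1e-12 and a > 0 and a * np.nanmax(means) ** 2 > 0.5 * var_span:
        raise RuntimeError(
            "analysis failure: convex (non-concave) variance-mean relation "
            f"(fit coefficients {coeffs})"
        )
    unitary = float(b)
    n_open = float(amps.mean() / unitary) if unitary > 1e-12 else float("inf")
    conductance_ps = unitary / driving_force_mv * 1e3  # pA/mV = nS -> pS
    return MeanVarianceResult(
        bin_means_pa=means,
        bin_variances_pa2=variances,
        unitary_current_pa=unitary,
        single_channel_conductance_ps=float(conductance_ps),
        open_channel_number=n_open,
        fit_coeffs=coeffs,
    )


def paired_pulse_ratio(first_peaks_pa, second_peaks_pa) -> float:
    """Mean peak EPSC of the second pulse over the first (>= 5 trials)."""
    p1 = np.asarray(first_peaks_pa, dtype=float)
    p2 = np.asarray(second_peaks_pa, dtype=float)
    if p1.size < 5 or p2.size < 5:
        raise ValueError("paired-pulse ratio needs at least 5 trials")
    if p1.mean() == 0:
        raise ValueError("undefined PPR: zero first-pulse mean")
    return float(p2.mean() / p1.mean())


def inv_cv2(peaks_pa) -> float:
    """1/CV^2 = (mean/SD)^2 of peak EPSC amplitudes (>= 20 trials).

    A presynaptic-efficacy measure; infinite (flagged by returning inf) for
    zero-variance responses.
    """
    p = np.asarray(peaks_pa, dtype=float)
    if p.size < 20:
        raise ValueError("1/CV^2 needs at least 20 trials")
    sd = p.std(ddof=1)
    if sd == 0:
        return float("inf")
    return float((p.mean() / sd) ** 2)


def io_curve_invivo(
    trace: np.ndarray,
    dt_ms: float,
    threshold_mv: float,
    v_rest_mv: float,
    bin_ms: float = 100.0,
    group_width: float = 0.1,
):
    """In vivo input-output curve from a current-clamp trace.

    The trace is parsed into ``bin_ms`` bins; per bin, spikes are counted
    (threshold-crossing onsets) and the median subthreshold potential,
    normalized as (V - V_rest) / (V_threshold - V_rest), is computed after
    spike clipping. Bins are grouped by normalized depolarization in
    ``group_width``-wide groups (0-0.1, 0.1-0.2, ...); per group the mean
    spike rate and P(>= 1 spike) = (bins with spikes) / (bins in group) are
    returned as a list of dicts.
    """
    if threshold_mv <= v_rest_mv:
        raise ValueError("threshold must exceed v_rest")
    v = np.asarray(trace, dtype=float)
    n_bin = int(round(bin_ms / dt_ms))
    n_bins = v.size // n_bin
    above = v >= threshold_mv
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    spike_counts = np.zeros(n_bins, dtype=int)
    for o in onsets:
        b = o // n_bin
        if b < n_bins:
            spike_counts[b] += 1
    masked = np.where(above, np.nan, v)
    depol = np.empty(n_bins)
    for b in range(n_bins):
        seg = masked[b * n_bin : (b + 1) * n_bin]
        med = np.nanmedian(seg)
        depol[b] = (med - v_rest_mv) / (threshold_mv - v_rest_mv)
    groups = np.floor(depol / group_width).astype(int)
    out = []
    for g in sorted(set(groups[np.isfinite(depol)])):
        in_g = groups == g
        n_g = int(in_g.sum())
        rate = spike_counts[in_g].mean() / (bin_ms / 1000.0)
        p_spike = float((spike_counts[in_g] > 0).mean())
        out.append(
            {
                "group": (g * group_width, (g + 1) * group_width),
                "n_bins": n_g,
                "mean_rate_hz": float(rate),
                "p_spike": p_spike,
                "mean_norm_depol": float(depol[in_g].mean()),
            }
        )
    return out
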