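"""Orientation tuning analysis for visual cortical responses.

Covers the response-quantification chain used for two-photon calcium imaging
and current-clamp data: dF/F computation, grating response extraction,
constrained Gaussian tuning fits (single for orientation, double for
direction), orientation selectivity (1 - circular variance), BIC-based
responsiveness classification, and a Gaussian-noise model that converts
subthreshold tuning plus trial-to-trial variability into a predicted
spike-probability tuning curve.

Orientation is treated as 180-degree periodic throughout via the wrapped
angular metrics ``ang_ori`` / ``ang_dir``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

__all__ = [
    "TuningFit",
    "SubthresholdTuningModel",
    "ang_ori",
    "ang_dir",
    "dff",
    "calcium_grating_response",
    "fit_orientation_gaussian",
    "fit_direction_double_gaussian",
    "osi",
    "bic_responsive",
    "movie_responsive",
    "gaussian_noise_spike_model",
]

#: sigma values (deg) used to initialize tuning fits
SIGMA_INITS = (10.0, 20.0, 40.0, 80.0, 160.0)

#: floor applied to the mean residual sum of squares inside BIC
VARIANCE_FLOOR = 1e-12


def ang_ori(x):
    """Wrapped orientation difference, constrained to 0-90 degrees.

    ``min(|x|, |x - 180|, |x + 180|)``; identical for angles 180 deg apart.
    """
    x = np.asarray(x, dtype=float)
    return np.abs(((x + 90.0) % 180.0) - 90.0)


def ang_dir(x):
    """Wrapped direction difference, constrained to 0-180 degrees."""
    x = np.asarray(x, dtype=float)
    return np.abs(((x + 180.0) % 360.0) - 180.0)


@dataclass
class TuningFit:
    """Result of a constrained Gaussian tuning fit.

    ``width_deg`` is the standard deviation (sigma) of the fitted curve — the
    conventional tuning-width measure. ``r_null`` is only populated by the
    double (direction) fit.
    """

    offset: float
    r_pref: float
    theta_pref_deg: float
    width_deg: float
    residual_ss: float
    kind: str
    r_null: float = 0.0

    def predict(self, theta_deg):
        theta_deg = np.asarray(theta_deg, dtype=float)
        if self.kind == "single":
            d = ang_ori(theta_deg - self.theta_pref_deg)
            return self.offset + self.r_pref * np.exp(-(d**2) / (2 * self.width_deg**2))
        d1 = ang_dir(theta_deg - self.theta_pref_deg)
        d2 = ang_dir(theta_deg - self.theta_pref_deg - 180.0)
        g = lambda d, a: a * np.exp(-(d**2) / (2 * self.width_deg**2))
        return self.offset + g(d1, self.r_pref) + g(d2, self.r_null)


def dff(raw: np.ndarray, fs_hz: float) -> np.ndarray:
    """Compute dF/F from a raw fluorescence time series.

    Baseline F0 is the 5th percentile of the low-passed trace (1 Hz cutoff,
    zero-phase 60th-order FIR filter); output is (F - F0) / F0. Invariant to
    multiplying the raw trace by a positive constant.
    """
    raw = np.asarray(raw, dtype=float)
    if fs_hz < 2.0:
        raise ValueError("sampling rate must be at least 2 Hz")
    taps = signal.firwin(61, 1.0, fs=fs_hz)
    padlen = min(3 * len(taps), raw.size - 1)
    smoothed = signal.filtfilt(taps, [1.0], raw, padlen=padlen)
    f0 = np.percentile(smoothed, 5)
    if f0 <= 0:
        raise ValueError("invalid baseline: F0 <= 0")
    return (raw - f0) / f0


def calcium_grating_response(
    dff_trace: np.ndarray,
    fs_hz: float,
    stim_onset_s: float,
    response_period_s: float = 4.0,
    window_s: float = 2.0,
    baseline_s: float = 1.0,
) -> float:
    """Visual response of a calcium trace to one grating presentation.

    Slow indicator kinetics motivate a 4 s response period (2 s grating plus
    the following 2 s of gray). The response is the highest mean dF/F over any
    sliding ``window_s`` window within that period, minus the mean dF/F in the
    ``baseline_s`` window immediately before stimulus onset.
    """
    x = np.asarray(dff_trace, dtype=float)
    i_on = int(round(stim_onset_s * fs_hz))
    n_win = max(1, int(round(window_s * fs_hz)))
    n_base = max(1, int(round(baseline_s * fs_hz)))
    n_resp = int(round(response_period_s * fs_hz))
    if i_on - n_base < 0 or i_on + n_resp > x.size:
        raise IndexError("response/baseline window exceeds trace bounds")
    baseline = x[i_on - n_base : i_on].mean()
    seg = x[i_on : i_on + n_resp]
    if n_win >= seg.size:
        best = seg.mean()
    else:
        csum = np.concatenate(([0.0], np.cumsum(seg)))
        means = (csum[n_win:] - csum[:-n_win]) / n_win
        best = means.max()
    return float(best - baseline)


def _best_fit(residual_fn, inits, bounds):
    best = None
    for x0 in inits:
        try:
            res = optimize.least_squares(residual_fn, x0, bounds=bounds)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("tuning fit failed for all initializations")
    return best


def fit_orientation_gaussian(
    orientations_deg: np.ndarray,
    responses: np.ndarray,
    fix_offset_zero: bool = True,
) -> TuningFit:
    """Fit a single wrapped Gaussian to per-orientation mean responses.

    R(theta) = C + Rp * exp(-ang_ori(theta - theta_pref)^2 / (2 sigma^2)),
    with Rp constrained to [pref/2, pref] where pref is the mean response at
    the empirically preferred orientation, and C fixed to 0 for dF/F data
    (``fix_offset_zero=True``, the default) or free otherwise. The fit is
    initialized at several sigma values; the lowest-SSE fit wins.
    """
    th = np.asarray(orientations_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if th.size < 4:
        raise ValueError("need at least 4 distinct orientations")
    pref_resp = float(r.max())
    if pref_resp <= 0:
        raise RuntimeError("fit failure: non-positive preferred response")
    th_pref0 = float(th[np.argmax(r)])

    def model(p):
        c, rp, th_p, sig = p
        d = ang_ori(th - th_p)
        return c + rp * np.exp(-(d**2) / (2 * sig**2))

    lo_c, hi_c = (0.0, 1e-12) if fix_offset_zero else (-np.inf, np.inf)
    bounds = (
        [lo_c, pref_resp / 2.0, th_pref0 - 90.0, 1.0],
        [hi_c, pref_resp, th_pref0 + 90.0, 1e3],
    )
    inits = [
        np.array([0.0 if fix_offset_zero else float(r.min()),
                  0.75 * pref_resp, th_pref0, s])
        for s in SIGMA_INITS
    ]
    best = _best_fit(lambda p: model(p) - r, inits, bounds)
    c, rp, th_p, sig = best.x
    th_p = ((th_p + 90.0) % 180.0) - 90.0
    return TuningFit(
        offset=float(c),
        r_pref=float(rp),
        theta_pref_deg=float(th_p),
        width_deg=float(sig),
        residual_ss=float(2 * best.cost),
        kind="single",
    )


def fit_direction_double_gaussian(
    directions_deg: np.ndarray,
    responses: np.ndarray,
    fix_offset_zero: bool = True,
) -> TuningFit:
    """Fit a double wrapped Gaussian to per-direction mean responses.

    Two Gaussians of shared width sit at the preferred direction and at the
    opposite (null) direction, 180 degrees away; amplitudes Rp (preferred) and
    Rn (null) are constrained to [pref/2, pref] and [0, Rp] respectively.
    """
    th = np.asarray(directions_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if th.size < 8:
        raise ValueError("need at least 8 directions")
    pref_resp = float(r.max())
    if pref_resp <= 0:
        raise RuntimeError("fit failure: non-positive preferred response")
    th_pref0 = float(th[np.argmax(r)])

    def model(p):
        c, rp, rn, th_p, sig = p
        d1 = ang_dir(th - th_p)
        d2 = ang_dir(th - th_p - 180.0)
        e = lambda d: np.exp(-(d**2) / (2 * sig**2))
        return c + rp * e(d1) + rn * e(d2)

    lo_c, hi_c = (0.0, 1e-12) if fix_offset_zero else (-np.inf, np.inf)
    bounds = (
        [lo_c, pref_resp / 2.0, 0.0, th_pref0 - 180.0, 1.0],
        [hi_c, pref_resp, pref_resp, th_pref0 + 180.0, 1e3],
    )
    inits = [
        np.array([0.0 if fix_offset_zero else float(r.min()),
                  0.75 * pref_resp, 0.25 * pref_resp, th_pref0, s])
        for s in SIGMA_INITS
    ]
    best = _best_fit(lambda p: model(p) - r, inits, bounds)
    c, rp, rn, th_p, sig = best.x
    th_p = ((th_p + 180.0) % 360.0) - 180.0
    return TuningFit(
        offset=float(c),
        r_pref=float(rp),
        theta_pref_deg=float(th_p),
        width_deg=float(sig),
        residual_ss=float(2 * best.cost),
        kind="double",
        r_null=float(rn),
    )


def osi(orientations_deg: np.ndarray, responses: np.ndarray) -> float:
    """Orientation selectivity index: 1 minus circular variance.

    OSI = | sum_k R(theta_k) e^{2 i theta_k} / sum_k R(theta_k) |, computed on
    the mean response to each presented orientation; negative responses are
    floored at zero before use. 1 for a single nonzero response, 0 for
    uniform responses over evenly spaced orientations.
    """
    th = np.deg2rad(np.asarray(orientations_deg, dtype=float))
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    total = r.sum()
    if total == 0:
        raise ValueError("undefined OSI: responses sum to zero")
    return float(np.abs(np.sum(r * np.exp(2j * th)) / total))


def bic_responsive(
    directions_deg: np.ndarray,
    trial_responses: np.ndarray,
    threshold: float = 10.0,
) -> tuple[bool, float]:
    """Classify a neuron as grating-responsive by BIC model comparison.

    ``trial_responses`` has shape (n_directions, n_trials). The double
    Gaussian (fit to per-direction means, k = 4 free parameters with the
    offset fixed at 0) is compared against a flat-zero null (k = 0) using
    BIC = n ln(mean residual SS) + k ln(n) over all individual trial
    responses. Responsive iff BIC_null - BIC_gaussian >= ``threshold``
    (default 10, strong evidence). The mean residual SS is floored to keep
    BIC finite on perfect fits.

    Returns (responsive, delta_bic).
    """
    th = np.asarray(directions_deg, dtype=float)
    y = np.asarray(trial_responses, dtype=float)
    if y.ndim != 2 or y.shape[0] != th.size:
        raise ValueError("trial_responses must be (n_directions, n_trials)")
    n = y.size
    k_gauss = 4  # Rp, Rn, theta_pref, sigma (offset fixed at 0)
    if n < k_gauss + 2:
        raise ValueError("too few responses for model comparison")
    means = y.mean(axis=1)
    if means.max() <= 0:
        # degenerate: nothing to fit; the null cannot lose
        return False, 0.0
    try:
        fit = fit_direction_double_gaussian(th, means, fix_offset_zero=True)
        pred = fit.predict(th)
    except (RuntimeError, ValueError):
        return False, 0.0
    ss_gauss = max(np.mean((y - pred[:, None]) ** 2), VARIANCE_FLOOR)
    ss_null = max(np.mean(y**2), VARIANCE_FLOOR)
    bic_gauss = n * np.log(ss_gauss) + k_gauss * np.log(n)
    bic_null = n * np.log(ss_null)
    delta = float(bic_null - bic_gauss)
    return delta >= threshold, delta


def movie_responsive(binned_rates: np.ndarray, criterion_sd: float = 5.0) -> bool:
    """Whether a neuron responds to any 1 s movie bin at >= 5 SD.

    ``binned_rates`` has shape (n_bins, n_trials). True iff some bin's mean
    response is at least ``criterion_sd`` times the across-trial SD of that
    bin. Zero SDs are floored at machine epsilon so deterministic positive
    responses count as responsive (the limiting case of the rule).
    """
    x = np.asarray(binned_rates, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need (n_bins, n_trials) with at least 2 trials")
    means = x.mean(axis=1)
    sds = np.maximum(x.std(axis=1, ddof=1), np.finfo(float).eps)
    return bool(np.any(means >= criterion_sd * sds))


@dataclass
class SubthresholdTuningModel:
    """Inputs to the Gaussian-noise spike-probability model.

    ``mu`` holds mean subthreshold depolarizations per orientation (normalized
    to the distance to spike threshold, so ``v_threshold`` defaults to 1);
    ``cv`` is the single trial-to-trial coefficient of variation, assumed
    constant across orientations, so sigma(theta) = cv * mu(theta).
    """

    orientations_deg: np.ndarray
    mu: np.ndarray
    cv: float
    v_threshold: float = 1.0


def gaussian_noise_spike_model(
    model: SubthresholdTuningModel,
    use_tail_probability: bool = False,
) -> tuple[np.ndarray, float]:
    """Predicted spike-probability tuning from subthreshold tuning plus noise.

    For each orientation the likelihood of the spike-threshold value under
    N(mu(theta), cv * mu(theta)) is evaluated (Gaussian density at threshold;
    ``use_tail_probability`` switches to the survival function for sensitivity
    analysis only) and normalized to the preferred orientation. A Gaussian is
    then fitted to the normalized curve and its sigma returned.

    Returns (normalized probabilities, fitted width in degrees). Width is
    monotone non-decreasing in ``cv`` for fixed mu.
    """
    mu = np.asarray(model.mu, dtype=float)
    th = np.asarray(model.orientations_deg, dtype=float)
    if model.cv <= 0:
        raise ValueError("degenerate density: cv must be positive")
    if mu.max() <= 0:
        raise ValueError("mu at the preferred orientation must be positive")
    sigma = model.cv * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (model.v_threshold - mu) / sigma
        if use_tail_probability:
            from scipy.stats import norm

            like = norm.sf(z)
        else:
            like = np.exp(-0.5 * z**2) / (sigma * np.sqrt(2 * np.pi))
    like = np.where(mu > 0, like, 0.0)
    pref = like[np.argmax(mu)]
    if pref <= 0:
        raise ValueError("degenerate output: zero likelihood at preferred")
    p = like / pref
    fit = fit_orientation_gaussian(th, p, fix_offset_zero=True)
    return p, fit.width_deg
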