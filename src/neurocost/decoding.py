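"""Leave-one-out maximum-likelihood population decoding.

Decodes stimulus identity (grating orientations or 1 s natural-scene bins)
from neuron x stimulus x trial response tensors. For each held-out trial the
per-neuron, per-stimulus response mean and SD are estimated from the
remaining trials; the held-out population response is assigned to the
stimulus maximizing the summed Gaussian log-likelihood across neurons.
Accuracy is averaged over trials, stimuli and random neuron subsamples.

Also provides the pixel-level scene dissimilarity score and the simulated
orientation-set decoding used to predict fine-discrimination thresholds from
fitted tuning curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tuning import TuningFit

__all__ = [
    "PopulationResponses",
    "DecoderResult",
    "SceneSet",
    "loo_ml_decode",
    "decode_scenes",
    "scene_dissimilarity",
    "simulate_orientation_decoding",
]

#: relative sigma floor (fraction of the population dynamic range)
SIGMA_FLOOR_FRACTION = 1e-6


@dataclass
class PopulationResponses:
    """Response tensor of shape (n_neurons, n_stimuli, n_trials).

    Responses may be dF/F values or binned spike rates. ``labels`` names the
    stimuli (orientation in degrees, or scene identifiers); ``truth`` records
    generating parameters for synthetic populations.
    """

    responses: np.ndarray
    labels: list
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (n_neurons, n_stimuli, n_trials)")
        if self.responses.shape[2] < 2:
            raise ValueError("leave-one-out needs at least 2 trials per stimulus")
        if len(self.labels) != self.responses.shape[1]:
            raise ValueError("labels must match the stimulus axis")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]


@dataclass
class DecoderResult:
    """Decoding accuracy plus per-stimulus confusion counts."""

    accuracy: float
    confusion: np.ndarray
    n_neurons: int
    n_resamples: int


def _loo_stats(x: np.ndarray):
    """Per-(neuron, stimulus) full-sample and leave-one-out mean/SD.

    ``x`` is (n, s, t). Returns full (mu, sd) of shape (n, s) and
    leave-one-out (mu, sd) of shape (n, s, t) where entry t excludes trial t.
    Sample (n-1 denominator) SDs throughout.
    """
    n_tr = x.shape[2]
    s1 = x.sum(axis=2)
    s2 = (x**2).sum(axis=2)
    mu_full = s1 / n_tr
    var_full = (s2 - n_tr * mu_full**2) / (n_tr - 1)
    sd_full = np.sqrt(np.clip(var_full, 0.0, None))
    mu_loo = (s1[:, :, None] - x) / (n_tr - 1)
    if n_tr > 2:
        var_loo = (s2[:, :, None] - x**2 - (n_tr - 1) * mu_loo**2) / (n_tr - 2)
    else:
        var_loo = np.zeros_like(x)
    sd_loo = np.sqrt(np.clip(var_loo, 0.0, None))
    return mu_full, sd_full, mu_loo, sd_loo


def _decode_tensor(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Confusion matrix (true x decoded counts) for one neuron subset."""
    n, s, t = x.shape
    mu_full, sd_full, mu_loo, sd_loo = _loo_stats(x)
    rng_span = float(np.ptp(x))
    floor = SIGMA_FLOOR_FRACTION * max(rng_span, 1.0)
    sd_full = np.maximum(sd_full, floor)
    sd_loo = np.maximum(sd_loo, floor)
    confusion = np.zeros((s, s), dtype=int)
    for si in range(s):
        for ti in range(t):
            obs = x[:, si, ti]  # (n,)
            mu = mu_full.copy()
            sd = sd_full.copy()
            mu[:, si] = mu_loo[:, si, ti]
            sd[:, si] = sd_loo[:, si, ti]
            z = (obs[:, None] - mu) / sd
            ll = -0.5 * z**2 - np.log(sd)
            total = ll.sum(axis=0)
            best = np.flatnonzero(total == total.max())
            decoded = best[0] if best.size == 1 else rng.choice(best)
            confusion[si, decoded] += 1
    return confusion


def loo_ml_decode(
    pop: PopulationResponses,
    n_sample: int | None = 50,
    n_resample: int = 100,
    seed: int = 0,
) -> DecoderResult:
    """Leave-one-out maximum-likelihood decoding accuracy.

    ``n_sample`` neurons are drawn without replacement from the population for
    each of ``n_resample`` subsets (subsets may overlap across resamples);
    accuracy is averaged per stimulus, then across stimuli and resamples.
    Pass ``n_sample=None`` to use the whole population once.

    Zero (neuron, stimulus) SDs are floored at a fraction of the population
    dynamic range; likelihood ties are broken uniformly at random under the
    run's seed.
    """
    x = pop.responses
    rng = np.random.default_rng(seed)
    if n_sample is None or n_sample == pop.n_neurons:
        subsets = [np.arange(pop.n_neurons)]
    else:
        if n_sample > pop.n_neurons:
            raise ValueError("n_sample exceeds the neuron count")
        subsets = [
            rng.choice(pop.n_neurons, size=n_sample, replace=False)
            for _ in range(n_resample)
        ]
    confusion = np.zeros((x.shape[1], x.shape[1]), dtype=float)
    accs = []
    for idx in subsets:
        c = _decode_tensor(x[idx], rng)
        confusion += c
        per_stim = np.diag(c) / c.sum(axis=1)
        accs.append(per_stim.mean())
    return DecoderResult(
        accuracy=float(np.mean(accs)),
        confusion=confusion,
        n_neurons=len(subsets[0]),
        n_resamples=len(subsets),
    )


def decode_scenes(
    pop: PopulationResponses,
    mode: str = "fine",
    environment_labels: list | None = None,
    n_sample: int | None = None,
    n_resample: int = 100,
    seed: int = 0,
) -> DecoderResult:
    """Decode natural-scene bins from binned spike-rate responses.

    ``mode='fine'``: the decoder must pick the exact scene bin (chance 1/58
    for a 58-scene movie). ``mode='coarse'``: scenes come from two
    environments (29 + 29 bins) and a trial is correct if the decoded scene
    belongs to the same environment as the tested scene (chance 1/2).
    ``environment_labels`` (one per stimulus) is required for coarse mode.
    """
    if mode not in ("fine", "coarse"):
        raise ValueError("mode must be 'fine' or 'coarse'")
    res = loo_ml_decode(pop, n_sample=n_sample, n_resample=n_resample, seed=seed)
    if mode == "fine":
        return res
    if environment_labels is None or len(environment_labels) != len(pop.labels):
        raise ValueError("coarse mode needs one environment label per stimulus")
    env = np.asarray(environment_labels)
    same_env = env[:, None] == env[None, :]
    correct = (res.confusion * same_env).sum(axis=1)
    per_stim = correct / res.confusion.sum(axis=1)
    return DecoderResult(
        accuracy=float(per_stim.mean()),
        confusion=res.confusion,
        n_neurons=res.n_neurons,
        n_resamples=res.n_resamples,
    )


@dataclass
class SceneSet:
    """Grayscale scene frames (8-bit) with scene-bin and environment labels."""

    frames: np.ndarray
    bin_labels: list
    environment_labels: list

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_scenes, height, width)")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")


def scene_dissimilarity(scenes: SceneSet, pairing: str = "within") -> float:
    """Mean absolute pixel difference over designated scene pairs.

    ``pairing='within'`` averages over all unordered pairs of scenes from the
    same environment; ``'between'`` over all pairs from different
    environments. Pixel intensities are on the native 0-255 scale.
    """
    frames = scenes.frames.astype(float)
    env = np.asarray(scenes.environment_labels)
    n = frames.shape[0]
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            same = env[i] == env[j]
            if (pairing == "within" and same) or (pairing == "between" and not same):
                diffs.append(np.abs(frames[i] - frames[j]).mean())
    if not diffs:
        raise ValueError(f"no scene pairs for pairing='{pairing}'")
    return float(np.mean(diffs))


def simulate_orientation_decoding(
    fits: list[TuningFit],
    pooled_cv: float,
    spacings_deg=(5.0, 7.5, 10.0, 15.0, 20.0, 30.0),
    n_trials: int = 10,
    n_rep: int = 1000,
    seed: int = 0,
) -> dict[float, float]:
    """Decoding accuracy on simulated orientation sets of varying spacing.

    Each neuron's fitted tuning curve supplies mu(theta); its trial SD is
    mu(theta) * ``pooled_cv`` (the across-orientation mean CV). For each
    spacing, orientations spanning 0-180 deg at that interval are defined,
    Gaussian responses generated, and leave-one-out ML decoding applied; the
    procedure is repeated ``n_rep`` times and averaged. Finer spacings are
    harder, so accuracy grows with spacing.
    """
    if pooled_cv < 0:
        raise ValueError("pooled_cv must be non-negative")
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for spacing in spacings_deg:
        n_ori = int(np.floor(180.0 / spacing))
        thetas = np.arange(n_ori) * spacing
        mu = np.stack([f.predict(thetas) for f in fits])  # (n_neurons, n_ori)
        mu = np.clip(mu, 1e-9, None)
        sd = np.maximum(pooled_cv * mu, 1e-12)
        accs = np.empty(n_rep)
        for r in range(n_rep):
            x = rng.normal(
                mu[:, :, None], sd[:, :, None], size=mu.shape + (n_trials,)
            )
            pop = PopulationResponses(x, labels=list(thetas))
            accs[r] = loo_ml_decode(
                pop, n_sample=None, seed=int(rng.integers(2**31))
            ).accuracy
        out[float(spacing)] = float(accs.mean())
    return out
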