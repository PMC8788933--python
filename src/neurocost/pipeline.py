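"""Config-driven end-to-end runs: synthesize, analyze, decode, report.

A run is described by a YAML (or dict) config with a global seed and a list
of stages; each stage writes CSV/JSON outputs into the run directory and is
recorded — with its seed, inputs, outputs and wall time — in a JSON run
manifest. Re-running the same config and seed reproduces all deterministic
outputs byte-for-byte. All randomness flows from the global seed through
named per-stage substreams; no stage touches global RNG state.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biophys, decoding, energetics, ephys, fileio, synth, tuning

__all__ = ["run", "report", "load_config"]

_STAGES = {}


def _stage(name):
    def deco(fn):
        _STAGES[name] = fn
        return fn

    return deco


def load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as f:
        return yaml.safe_load(f)


def _stage_seed(global_seed: int, stage_name: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run(config, out_dir=None) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    ``config`` is a dict or a path to a YAML file with keys ``seed``,
    ``out_dir`` and ``stages`` (list of ``{name: <stage>, params: {...}}``).
    Known stages: ``synth_population``, ``tuning_fit``, ``decode``,
    ``energy``, ``if_compensation``, ``hh_group_cv``.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "runs/latest"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __import__("neurocost").__version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "global_seed": seed,
        "stages": [],
    }
    context: dict = {}
    for stage_cfg in cfg.get("stages", []):
        name = stage_cfg["name"]
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        params = stage_cfg.get("params", {})
        stage_seed = _stage_seed(seed, name)
        t0 = time.perf_counter()
        try:
            outputs = _STAGES[name](params, stage_seed, out, context)
        except Exception as err:
            manifest["stages"].append(
                {"name": name, "seed": stage_seed, "error": repr(err)}
            )
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest["stages"].append(
            {
                "name": name,
                "seed": stage_seed,
                "params": params,
                "outputs": [str(p) for p in outputs],
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)


@_stage("synth_population")
def _synth_population(params, seed, out, context):
    pop = synth.gen_population_responses(
        n_neurons=params.get("n_neurons", 60),
        stimuli=params.get("stimuli", list(np.arange(0.0, 180.0, 15.0))),
        tuning_width_deg=params.get("tuning_width_deg", 30.0),
        response_cv=params.get("response_cv", 0.3),
        n_trials=params.get("n_trials", 10),
        seed=seed,
    )
    path = out / "population.csv"
    fileio.write_population_csv(path, pop)
    context["population"] = pop
    return [path]


@_stage("tuning_fit")
def _tuning_fit(params, seed, out, context):
    pop = context.get("population")
    if pop is None:
        pop = fileio.read_population_csv(out / "population.csv")
    rows = []
    thetas = np.asarray(pop.labels, dtype=float)
    for i in range(pop.n_neurons):
        means = pop.responses[i].mean(axis=1)
        responsive, dbic = tuning.bic_responsive(thetas, pop.responses[i])
        row = {"neuron": i, "delta_bic": dbic, "responsive": responsive}
        try:
            fit = tuning.fit_orientation_gaussian(thetas, means)
            row.update(
                theta_pref_deg=fit.theta_pref_deg,
                width_deg=fit.width_deg,
                osi=tuning.osi(thetas, means),
            )
        except (RuntimeError, ValueError):
            pass
        rows.append(row)
    path = out / "tuning_fits.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    context["tuning_fits"] = rows
    return [path]


@_stage("decode")
def _decode(params, seed, out, context):
    pop = context.get("population")
    if pop is None:
        pop = fileio.read_population_csv(out / "population.csv")
    res = decoding.loo_ml_decode(
        pop,
        n_sample=params.get("n_neurons", None),
        n_resample=params.get("n_resamples", 20),
        seed=seed,
    )
    path = out / "decoding.json"
    with open(path, "w") as f:
        json.dump(
            {
                "accuracy": res.accuracy,
                "n_neurons": res.n_neurons,
                "n_resamples": res.n_resamples,
                "chance": 1.0 / len(pop.labels),
            },
            f,
            indent=2,
        )
    conf_path = out / "confusion.csv"
    pd.DataFrame(res.confusion, index=pop.labels, columns=pop.labels).to_csv(conf_path)
    context["decoding_accuracy"] = res.accuracy
    return [path, conf_path]


@_stage("energy")
def _energy(params, seed, out, context):
    cells = params.get("cells")
    if cells is None:
        in_csv = params.get("in_csv")
        cells = pd.read_csv(in_csv).to_dict("records") if in_csv else []
    rows = []
    for cell in cells:
        rows.append(
            {
                **cell,
                "atp_synaptic_per_s": energetics.atp_rate_synaptic(
                    cell["stim_charge_rate_pa"], cell["baseline_charge_rate_pa"]
                ),
                "atp_spiking_per_s": energetics.atp_rate_spiking(
                    cell["spike_rate_hz"], cell["capacitance_pf"]
                ),
                "atp_resting_per_s": energetics.atp_rate_resting(
                    cell["input_resistance_mohm"], cell["v_rest_mv"]
                ),
            }
        )
    path = out / "atp_rates.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


@_stage("if_compensation")
def _if_compensation(params, seed, out, context):
    res = biophys.if_compensation_curves(
        rheobase_fraction=params.get("rheobase_fraction", 0.70)
    )
    path = out / "if_compensation.csv"
    pd.DataFrame(
        {
            "g_fraction": res["grid"],
            "control": res["control"],
            "food_restricted_compensated": res["food_restricted"],
        }
    ).to_csv(path, index=False)
    context["if_max_abs_deviation"] = res["max_abs_deviation"]
    return [path]


@_stage("hh_group_cv")
def _hh_group_cv(params, seed, out, context):
    """Group comparison of subthreshold variability (the model's core
    result); emits the per-group CV table normalized to control."""
    mp = biophys.calibrate_channels()
    syn = biophys.SynapticInput()
    noise_kind = params.get("noise", "external")
    n_trials = params.get("n_trials", 100)
    target = params.get("target_norm_depol", biophys.MATCHED_NORM_DEPOL)
    if noise_kind == "external":
        sigma0 = params.get("sigma0_ns")
        if sigma0 is None:
            stoch = biophys.measure_group_cv(
                biophys.group_params(mp, "control"),
                syn,
                biophys.NoiseModel("stochastic_channel"),
                n_trials=max(20, n_trials // 2),
                seed=seed,
                target_norm_depol=target,
            )
            sigma0 = biophys.calibrate_sigma0(
                biophys.group_params(mp, "control"), syn, stoch["cv"], target
            )
        noise = biophys.NoiseModel("external", sigma0_ns=sigma0)
    else:
        noise = biophys.NoiseModel("stochastic_channel")
    rows = []
    cv_ctrl = None
    for grp in biophys.GROUPS:
        r = biophys.measure_group_cv(
            biophys.group_params(mp, grp),
            syn,
            noise,
            n_trials=n_trials,
            seed=seed,
            target_norm_depol=target,
        )
        if grp == "control":
            cv_ctrl = r["cv"]
        rows.append({"group": grp, **{k: v for k, v in r.items() if k != "n_trials"}})
    for row in rows:
        row["cv_normalized"] = row["cv"] / cv_ctrl
    path = out / f"group_cv_{noise_kind}.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    context["group_cv"] = {row["group"]: row["cv_normalized"] for row in rows}
    return [path]


def report(manifest_or_path, out_path=None) -> str:
    """Render a plain-markdown summary of a run manifest.

    Lists stages, seeds and wall times, and pulls headline numbers (group CV
    table, IF compensation deviation, decoding accuracy) from the stage
    outputs when present. Missing outputs produce warnings, not errors.
    """
    if isinstance(manifest_or_path, (str, Path)):
        mpath = Path(manifest_or_path)
        if mpath.is_dir():
            mpath = mpath / "manifest.json"
        with open(mpath) as f:
            manifest = json.load(f)
        base = mpath.parent
    else:
        manifest = manifest_or_path
        base = Path(".")
    lines = ["# neurocost run report", ""]
    lines.append(f"package version: {manifest.get('package_version', '?')}")
    lines.append(f"config hash: {manifest.get('config_hash', '?')}")
    lines.append(f"global seed: {manifest.get('global_seed', '?')}")
    lines.append("")
    if not manifest.get("stages"):
        lines.append("(empty manifest: no stages were run)")
    for st in manifest.get("stages", []):
        lines.append(
            f"- stage `{st['name']}` (seed {st['seed']}, "
            f"{st.get('wall_time_s', '?')} s)"
        )
        for o in st.get("outputs", []):
            lines.append(f"    - {o}")
        if "error" in st:
            lines.append(f"    - ERROR: {st['error']}")
    for st in manifest.get("stages", []):
        for o in st.get("outputs", []):
            p = Path(o)
            if not p.exists() and not p.is_absolute() and (base / p.name).exists():
                p = base / p.name
            if p.name.startswith("group_cv") and p.exists():
                df = pd.read_csv(p)
                lines.append("")
                lines.append("## Subthreshold CV by group (normalized to control)")
                for _, row in df.iterrows():
                    lines.append(f"- {row['group']}: {row['cv_normalized']:.3f}")
            elif not p.exists():
                lines.append(f"- WARNING: missing output {p}")
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
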