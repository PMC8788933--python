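"""End-to-end pipeline run from a YAML config.

Synthesizes a population, fits tuning, decodes, and renders the report.
Stage seeds derive from the single global seed, so re-running reproduces
every output byte-for-byte.
"""

from neurocost import pipeline

config = {
    "seed": 11,
    "out_dir": "runs/example",
    "stages": [
        {"name": "synth_population", "params": {"n_neurons": 40, "n_trials": 8}},
        {"name": "tuning_fit"},
        {"name": "decode", "params": {"n_resamples": 10}},
    ],
}
manifest = pipeline.run(config)
print(pipeline.report(manifest_or_path="runs/example"))
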