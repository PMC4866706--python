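"""Generate the default synthetic two-group myometrium study.

Writes the raw intensity matrix, negative-control list, sample metadata and
the ground-truth tables under results/run/.  The study mimics a 22-vs-26
bead-array comparison in which labouring samples carry a higher leukocyte
fraction (mean 0.30 vs 0.05), so part of the between-group signal is purely
compositional.
"""

from myolab.pipeline import RunConfig, run_pipeline

config = RunConfig(outdir="results/run", seed=1)
report = run_pipeline(config, stages=["simulate"])

sim = report["simulate"]
print(f"wrote study: {sim['n_probes']} probes x {sim['n_samples']} samples "
      f"({sim['n_control_probes']} negative controls) -> {config.outdir}/")
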