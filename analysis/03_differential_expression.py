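"""Rank-product differential expression with permutation PFP.

Calls a probe differential when its percentage-of-false-positives value is
at most 0.05 in one direction and its signed fold change clears 1.2 in
magnitude.  Writes the full DE table to results/run/de_table.tsv.
"""

import pandas as pd

from myolab.pipeline import RunConfig, run_pipeline

config = RunConfig(outdir="results/run", seed=1)
report = run_pipeline(config, stages=["de"])

de = report["de"]
print(f"tested {de['n_probes_tested']} probes at |FC| >= {de['fc_threshold']}, "
      f"PFP <= {de['pfp_alpha']}")
print(f"called: {de['n_up']} up, {de['n_down']} down in labour")

table = pd.read_csv("results/run/de_table.tsv", sep="\t")
top = table.sort_values("pfp_up").head(5)[["probe_id", "signed_fc", "pfp_up"]]
print("\nstrongest up-regulated probes:")
print(top.to_string(index=False))
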