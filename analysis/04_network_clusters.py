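"""Correlation-network graphs and Markov Clustering.

Builds the sample-sample graph (Pearson r > 0.85 over the top up/down
rank-product probes, MCL inflation 3.0) and the probe-probe co-expression
graph (r > 0.80, inflation 2.2), writes GraphML + cluster tables, and tests
whether sample clusters align with labour status.
"""

from myolab.pipeline import RunConfig, run_pipeline

config = RunConfig(outdir="results/run", seed=1)
report = run_pipeline(config, stages=["network"])

net = report["network"]
print(f"graph input: {net['n_selected_probes']} probes")
print(f"sample clusters: {net['sample_clusters']}  "
      f"(labour association {net['labour_association_test']} "
      f"p = {net['labour_association_p']:.2e})")
print(f"probe clusters: {net['probe_clusters']}")
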