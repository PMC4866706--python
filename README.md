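# myolab

A tested re-implementation of the complete computational workflow used to
compare bulk gene expression between labouring and non-labouring human
myometrium on bead arrays — preprocessing, rank-product differential
expression with a permutation percentage-of-false-positives (PFP)
correction, correlation-network clustering with a from-scratch Markov
Clustering (MCL) implementation, cross-study standardized-mean-difference
meta-analysis, and the internal validation procedures (subgroup sensitivity
analysis, delta-CT comparison, cross-platform concordance).

The package is aimed at anyone who wants to study how this class of
two-group transcriptome pipeline behaves — in particular how **tissue
composition** confounds it.  Labouring myometrium is infiltrated by
leukocytes, so muscle-restricted transcripts appear down-regulated and
leukocyte-restricted transcripts appear up-regulated even if no cell changes
its transcription.  Everything here therefore runs on synthetic studies from
a generative mixture model with known ground truth:

```
t_gs = [(1 - f_s) · mu_muscle_g + f_s · mu_leukocyte_g] · beta_g^{labour(s)}
y_gs = b_gs + scale_s · t_gs · exp(eps_gs)
```

where `f_s` is the sample's leukocyte fraction (Beta-distributed, group
means 0.05 non-labouring vs 0.30 labouring), `beta_g` a multiplicative
transcriptional labour effect, `eps_gs ~ N(0, 0.3)` log-scale noise and
`b_gs` an additive Gaussian background that negative-control probes receive
alone.

## Core statistics

* **Rank product**: for K labour × non-labour sample pairs, each probe's
  fold-change rank per pair is combined as `RP_g = (∏_k rank_gk)^{1/K}`.
  Significance comes from a permutation null that shuffles each probe's
  intensities across samples while keeping the pair structure fixed;
  `PFP_g = E[false positives at RP_g] / rank(RP_g)` is thresholded at 0.05
  together with a |fold change| ≥ 1.2 gate.
* **MCL**: column-stochastic transition matrix from the thresholded Pearson
  graph; iterate expansion (`M²`), inflation (elementwise power, MCLi 3.0
  for samples / 2.2 for probes) and pruning until a fixed point; clusters =
  connected components of the limit structure.
* **Meta-analysis**: per-study Hedges `g = J·(mean_L − mean_NL)/s_p` with
  `J = 1 − 3/(4·df − 1)`, pooled by inverse-variance weighting; fixed effect
  and DerSimonian–Laird random effects, with Cochran's Q and tau².

## Worked example

```
$ python analysis/01_simulate.py
wrote study: 2050 probes x 48 samples (100 negative controls) -> results/run/
$ python analysis/02_preprocess.py
detection floor: 100 (negative_control_median)
probes: 2050 in, 100 controls, 57 below floor, 1893 retained
$ python analysis/03_differential_expression.py
tested 1893 probes at |FC| >= 1.2, PFP <= 0.05
called: 183 up, 53 down in labour
$ python analysis/04_network_clusters.py
graph input: 200 probes
sample clusters: 22  (labour association chi_squared p = 6.88e-04)
$ python analysis/06_sensitivity.py
1893 probes; median |dFC| = 0.0762; IQR of signed dFC = (-0.081, 0.072)
FC correlation full vs reduced = 0.922; direction unchanged for 89.6% of probes
```

Reading those numbers: the detection floor lands on the configured
negative-control median (100 intensity units); the DE stage calls mostly
leukocyte-marker probes "up in labour" — the compositional signature —
while the sample network separates labouring from non-labouring samples
(association p ≈ 7e-4) and the sensitivity analysis confirms that dropping
the (effect-free) induced-labour subgroup leaves fold changes stable.
`analysis/05_meta_analysis.py` adds two smaller companion studies and pools
per-gene effects across all three.

The same stages are available as a CLI (`myolab simulate|preprocess|de|
network|meta|sensitivity|all --seed 1 --out results/run`) driven by an
optional YAML config whose defaults carry the conventional parameters
(floor 100, |FC| 1.2, PFP 0.05, sample r 0.85 / MCLi 3.0, probe r 0.80 /
MCLi 2.2).

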