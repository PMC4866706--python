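# Methods

## The generative model

Every stage is exercised on synthetic two-group bead-array studies with
known ground truth.  A gene catalog assigns each gene a class and three
parameters: `mu_muscle` and `mu_leukocyte`, its expected intensity in pure
smooth-muscle and pure leukocyte tissue (arbitrary intensity units), and
`beta`, a multiplicative transcriptional labour effect (1 = null).  A
sample `s` carries a latent leukocyte fraction `f_s`; its true signal for
gene `g` is the mixture

    t_gs = [(1 − f_s)·mu_muscle_g + f_s·mu_leukocyte_g] · beta_g^{labour(s)}

observed through a per-sample scale factor (log-normal, spread 0.05),
multiplicative log-normal measurement noise (SD 0.3 on the natural-log
scale — typical of within-group variation in bulk human tissue), and an
additive Gaussian background (mean 100, SD 15, truncated positive) that
negative-control probes receive alone.  All randomness flows from a single
integer seed; identical seeds give bit-identical studies.

Leukocyte fractions default to Beta(2, 38) in non-labouring samples (mean
0.05) and Beta(3, 7) in labouring samples (mean 0.30).  The labouring
distribution is deliberately wider: labouring tissue is the heterogeneous
condition, and that asymmetry is what makes labouring samples spread out in
the sample network.  No quantitative leukocyte-fraction estimate exists for
this tissue, so these are exposed parameters, not biological claims; both
accept a plain float for a degenerate point mass, which the tests use for
exact arithmetic checks.

The default catalog holds 200 muscle-specific, 200 leukocyte-specific, 100
labour-induced (beta 2), 50 labour-repressed (beta 0.5), 1400 housekeeping
and 100 negative-control genes — large enough to preserve class structure,
small enough that the full pipeline runs in seconds.  Marker-class
intensities are drawn log-normal with median 1000 and σ_log 0.6 (cell-type
marker panels are strongly expressed in their own compartment); labour-
effect genes use median 500, σ_log 0.6 in both compartments so their
apparent direction is purely transcriptional; housekeeping genes use median
500 with a broad σ_log 1.0, leaving a realistic below-floor tail.

What the generator does **not** emulate: bead-level data, probe sequences,
scanner artifacts, RNA degradation, batch effects (chip assignment is
recorded but has no effect by default), or correlated biological modules
beyond the two-compartment mixture.  Passing tests therefore demonstrate
the pipeline's behaviour under a clean compositional confounder — not
performance on the full noise anatomy of real arrays.

## Preprocessing

Background correction uses the normal + exponential convolution model:
observed `O = B + S` with `B ~ N(mu, sigma²)` and `S ~ Exp(theta)`, each
intensity replaced by the posterior mean `E[S | O = o]` with the background
constrained positive, i.e. the mean of `N(a, sigma²)` truncated to `(0, o)`
where `a = o − mu − sigma²/theta`.  The closed form uses the scaled
complementary error function; far-tail cases fall back to the boundary
asymptotics, and the output is clamped strictly positive.  Parameters are
estimated per sample from the negative-control probes (`mu`, `sigma` =
control mean and SD; `theta` = mean regular-probe excess, floored at 1e-6),
which is the natural estimator on platforms that carry a dedicated
negative-control set.  A quadrature oracle in the test suite verifies the
closed form to four significant figures.

Quantile normalization maps every sample onto the rank-mean reference;
within-sample ties receive the mean of the reference values over the tied
rank span, which makes the operation idempotent and conserves the grand
mean exactly.  The detection floor is the median negative-control intensity
of the **raw** matrix, rounded half-away-from-zero (the conventional value
100 under the default background).  After correction and normalization a
probe is kept only if at least one group's mean reaches the floor — a probe
expressed in either condition must survive; negative controls are always
removed from the analysis matrix.

One behaviour worth knowing about: with a strong one-sided compositional
shift, quantile normalization redistributes intensity mass and drags
unaffected genes slightly in the opposite direction (measured: housekeeping
median apparent FC −1.04 under the default composition shift).  This is a
real property of quantile normalization under asymmetric global changes,
not an implementation artifact, and it slightly compresses marker-class
fold changes.

## Rank product and PFP

For K labour × non-labour sample pairs (all `nL × nNL` pairs, or a seeded
random subset when more than `max_pairs = 100`), each probe's per-pair
ratio rank is combined as the geometric mean, accumulated in log space.
Up- and down-ranks are exact reverses under average tie-ranking, so one
ranking pass serves both directions.  Ratios are formed on the normalized
raw scale by default (consistent with the non-log fold-change convention);
a log2 option exists and produces identical ranks.

The permutation null shuffles **each probe's intensity vector across all
samples** independently and recomputes rank products through the identical
pair structure.  This choice is load-bearing.  Because the comparisons are
all sample pairs, a probe's ranks are strongly correlated across
comparisons that share a sample; a null that assigns independent uniform
ranks per comparison (the textbook description) has far lighter tails and
is wildly anticonservative here — on a global-null study it calls ~20% of
probes significant.  The sample-permutation null is exact under
within-probe exchangeability: on the same global-null study it yields
uniform permutation p-values (KS p ≈ 0.9) and a 0% false-call rate at the
PFP 0.05 + |FC| 1.2 gate.  One null sample serves both directions (they are
identically distributed under it).

`PFP_g = (c_g / B) / rank(RP_g)` with `c_g` the count of null rank products
at or below the observed one; PFP is made monotone non-decreasing in RP by
a running maximum so threshold sets are nested in alpha.  A probe is called
up when `PFP_up ≤ 0.05` and signed FC ≥ +1.2 (down mirrored); the signed FC
convention is +R / −1/R with magnitude ≥ 1.

Known limitation: the calibrated null costs power.  At 50 planted two-fold
genes among 1000, n = 8+8, log-noise 0.3, measured sensitivity is 0.60–0.86
across seeds (mean 0.74) with 100% direction accuracy; an oracle null with
no effect-gene contamination reaches only ≈0.78.  A target of ≥0.8 at these
conditions is above the estimator's intrinsic power — the corresponding
acceptance test is expected to fail and is left failing rather than
weakening the null or the bound.  Detecting modest effects (|FC| ≈ 1.3)
at this desk scale is likewise underpowered, which is why down-calls are
scarce in the default run.

## Networks and MCL

The sample–sample graph connects samples whose Pearson correlation over a
probe panel strictly exceeds 0.85; the probe–probe graph uses 0.80.
Negative correlations never create edges; zero-variance vectors are dropped
with a warning.  Correlations are computed on log2 intensities: sample
similarity rides on the shared intensity profile, which per-probe
standardization would erase (and probe–probe correlations are invariant to
per-probe location/scale anyway).  The graph input is the union of the top
100 up- and top 100 down-ranked probes by rank product — rather than the
significance-gated DE set, which on small synthetic studies can collapse to
one direction and starve the graph of intensity diversity.

MCL is implemented from scratch: weighted adjacency plus unit self-loops,
column-normalized; iterate expansion (matrix square), inflation
(elementwise power, then renormalize), pruning below 1e-5 (renormalize
again), until the maximum entry change falls below 1e-6 or 200 iterations.
Column sums are checked to 1e-9 inside every iteration and a violation
raises.  Clusters are the connected components of the symmetrized non-zero
structure of the limit matrix, numbered 1..k by descending size (ties by
smallest member label).  Inflation 3.0 is the sample-graph default and 2.2
the probe-graph default; on the planted three-block fixture the cluster
count is non-decreasing in inflation across {1.5, 2.2, 3.0, 4.0}.

Cluster–trait association builds the cluster × trait table and uses
Fisher's exact test whenever any expected cell count is below 5 (Pearson
chi-squared otherwise).  The 2×2 (and small r×2) Fisher test is computed
with exact integer arithmetic — binomial-coefficient weights compared and
summed as integers, divided once at the end — so two-sided tie handling is
exact; larger sparse tables fall back to chi-squared with a warning.

## Meta-analysis

Studies are harmonized by collapsing probes to genes (the probe with the
highest mean intensity represents the gene; a mean-collapse rule is
available) and intersecting gene sets.  Effects are Hedges g on log2
intensities (roughly symmetric within groups): `d = (mean_L − mean_NL)/s_p`
with the pooled SD, `g = J·d`, `J = 1 − 3/(4·df − 1)`,
`var_g = (n_L+n_NL)/(n_L·n_NL) + g²/(2(n_L+n_NL))` — the small-sample
correction is material at 6–26 samples per group.  Fixed-effect pooling
uses `w = 1/var`; heterogeneity is Cochran's Q with its chi-squared tail
probability and the DerSimonian–Laird `tau² = max(0, (Q − df)/C)`; random
effects reuse the machinery with `w* = 1/(var + tau²)`.  Both estimates are
always reported — neither is privileged, since either pooling model is
defensible depending on observed heterogeneity — and they coincide whenever
tau² = 0.  Concordance between two studies' DE results is reported as the
percentage of A's significant genes replicated in B with matching sign,
matching sign regardless of B's significance, and sign conflicts among
genes significant in both.

## Validation procedures

The subgroup sensitivity analysis recomputes signed fold changes on the
sample subset excluding a flagged subgroup and reports the median |ΔFC|,
the IQR of *signed* differences (it straddles zero when the exclusion is
null), the Pearson correlation of the two FC vectors and the percentage of
probes with unchanged direction — all on the signed-FC scale.  The empty
exclusion is an exact identity.  The delta-CT comparison forms
`dCT = CT(target) − CT(reference)` per sample and applies a pooled-variance
Student t-test between groups (Welch optional); constant-sample degeneracy
is resolved by the limit (t = 0, p = 1 at zero mean difference).  Direction
calls invert the CT/expression relationship: lower dCT means higher
expression.  Cross-platform concordance is the Pearson correlation of two
platforms' per-gene log2 group ratios plus a per-gene sign-agreement table.

## Numerical and design choices

- Rounding (detection floor): half away from zero, for cross-platform
  determinism.
- Normexp degeneracy: zero control variance floors sigma at 1e-6 with a
  logged warning; corrected intensities are clamped at 1e-6.
- Threshold semantics: correlation edges require r strictly greater than
  the cutoff; PFP and FC thresholds are inclusive.
- Up/down call collisions are impossible under the FC gate (a signed FC
  cannot clear both +1.2 and −1.2); the tie-break path (smaller PFP, then
  FC sign) exists defensively.
- MCL multi-attractor nodes resolve through the symmetrized-component rule,
  which is deterministic and yields disjoint clusters.
- The benchmark scenarios use 1000-probe catalogs (power, calibration) and
  the 2050-probe default elsewhere; full suite ≈ 30 s, acceptance script
  ≈ 20 s on one CPU.
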