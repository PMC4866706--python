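"""Self-contained benchmark scenarios exercising every pipeline stage.

Each function builds its own synthetic inputs from a seed, runs the package
end to end (or against an independent brute-force oracle) and returns the
measured quantities.  The acceptance test suite asserts on these numbers;
the acceptance script reports them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from .diffexp import RankProductConfig, estimate_pfp, rank_product, run_diffexp
from .meta import SMDRecord, pool, smd
from .network import MCLConfig, MODE_PROBE, correlation_graph, fisher_exact_2x2, mcl_cluster
from .pipeline import RunConfig, run_pipeline
from .preprocess import preprocess
from .simulate import MixtureParams, StudyDesign, default_catalog, generate_study
from .validation import subgroup_sensitivity


def _two_group_md(n_l: int, n_nl: int) -> pd.DataFrame:
    ids = [f"s{j}" for j in range(n_l + n_nl)]
    return pd.DataFrame(
        {"group": ["labour"] * n_l + ["nonlabour"] * n_nl},
        index=pd.Index(ids, name="sample_id"),
    )


def _wrap(values: np.ndarray) -> ExpressionMatrix:
    probes = [f"p{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        is_control=pd.Series(False, index=pd.Index(probes)),
    )


# ---------------------------------------------------------------------------
# rank product vs brute force; PFP vs exhaustive enumeration
# ---------------------------------------------------------------------------

def rank_product_oracle_error(seed: int = 0) -> dict:
    """Max relative deviation between the vectorized rank product and an
    explicit per-pair rank/product/K-th-root computation (20 probes, 3v3)."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(5, 1, size=(20, 6))
    m = _wrap(vals)
    md = _two_group_md(3, 3)
    got = rank_product(m, md, RankProductConfig(max_pairs=100, seed=seed))

    x_l, x_nl = vals[:, :3], vals[:, 3:]
    prod_up = np.ones(20)
    prod_down = np.ones(20)
    for i, j in itertools.product(range(3), range(3)):
        ratios = x_l[:, i] / x_nl[:, j]
        prod_down *= rankdata(ratios, method="average")
        prod_up *= rankdata(-ratios, method="average")
    want_up, want_down = prod_up ** (1 / 9), prod_down ** (1 / 9)
    err = max(
        np.max(np.abs(got["rp_up"].to_numpy() - want_up) / want_up),
        np.max(np.abs(got["rp_down"].to_numpy() - want_down) / want_down),
    )
    return {"max_rel_error": float(err), "n": 20}


def pfp_exhaustive_check(seed: int = 0, n_permutations: int = 2000) -> dict:
    """Monte-Carlo PFP on a 4-probe, 2-comparison instance vs exhaustive
    enumeration of the permutation null.

    The null permutes each probe's sample vector independently, so the exact
    distribution enumerates all (4!)^4 joint per-probe permutations and
    recomputes the rank products through the same comparison structure.
    Returns the largest deviation of the Monte-Carlo expected-false-positive
    counts from the exact values, in Monte-Carlo standard-error units."""
    from .diffexp import _pair_indices

    rng = np.random.default_rng(seed)
    vals = rng.lognormal(3, 0.5, size=(4, 4))
    m = _wrap(vals)
    md = _two_group_md(2, 2)
    cfg = RankProductConfig(max_pairs=2, seed=seed, n_permutations=n_permutations)
    obs = rank_product(m, md, cfg)["rp_up"]
    pairs = _pair_indices(2, 2, cfg.max_pairs, np.random.default_rng(seed))

    perms = list(itertools.permutations(range(4)))  # 24 sample orders
    ratios_per_perm = np.empty((4, len(perms), len(pairs)))
    for g in range(4):
        for pi, perm in enumerate(perms):
            row = vals[g, list(perm)]
            for k, (i, j) in enumerate(pairs):
                ratios_per_perm[g, pi, k] = row[:2][i] / row[2:][j]

    combos = np.array(list(itertools.product(range(len(perms)), repeat=4)))
    # (n_combos, G, K) ratios under each joint permutation assignment
    ratios = ratios_per_perm[np.arange(4)[None, :], combos, :]
    down = rankdata(ratios, method="average", axis=1)
    up = 4 + 1 - down
    rp_null = np.exp(np.log(up).mean(axis=2))  # (n_combos, G)

    obs_arr = obs.to_numpy()
    counts = (rp_null[:, :, None] <= obs_arr[None, None, :]).sum(axis=1)
    e_exact = counts.mean(axis=0)
    se = counts.std(axis=0) / math.sqrt(n_permutations)

    mc = estimate_pfp(obs, m, md, cfg)["expected_fp"].to_numpy()
    dev = np.abs(mc - e_exact) / np.maximum(se, 1e-12)
    return {"max_se_deviation": float(dev.max()), "n": 4}


# ---------------------------------------------------------------------------
# type-I calibration and power
# ---------------------------------------------------------------------------

def null_calibration(seed: int = 0) -> dict:
    """Global-null study (1000 regular probes, 8+8 samples, B=100): fraction
    of probes called differential, and KS uniformity of the permutation
    p-values."""
    catalog = default_catalog(
        class_sizes={
            "muscle_specific": 0, "leukocyte_specific": 0,
            "labour_induced": 0, "labour_repressed": 0,
            "housekeeping": 1000, "negative_control": 100,
        },
        seed=seed,
    )
    mix = MixtureParams(f_labour=(2.0, 38.0), f_nonlabour=(2.0, 38.0))
    study = generate_study(catalog, mix, StudyDesign(n_labour=8, n_nonlabour=8, seed=seed))
    proc, _ = preprocess(study.expression, study.metadata)
    de = run_diffexp(proc, study.metadata, RankProductConfig(seed=seed, n_permutations=100))
    call_rate = float((de["call"] != "not_significant").mean())
    ks_up = stats.kstest(de["pvalue_up"], "uniform").pvalue
    ks_down = stats.kstest(de["pvalue_down"], "uniform").pvalue
    return {
        "call_rate": call_rate,
        "ks_p_up": float(ks_up),
        "ks_p_down": float(ks_down),
        "n": len(de),
    }


def power_recovery(seed: int = 0) -> dict:
    """50 genes planted at a 2-fold labour induction (n=8+8, log-noise 0.3):
    sensitivity of the up call and direction accuracy among planted genes."""
    catalog = default_catalog(
        class_sizes={
            "muscle_specific": 0, "leukocyte_specific": 0,
            "labour_induced": 50, "labour_repressed": 0,
            "housekeeping": 950, "negative_control": 100,
        },
        beta_induced=2.0,
        seed=seed,
    )
    mix = MixtureParams(
        f_labour=(2.0, 38.0), f_nonlabour=(2.0, 38.0), noise_sd_log=0.3
    )
    study = generate_study(catalog, mix, StudyDesign(n_labour=8, n_nonlabour=8, seed=seed))
    proc, _ = preprocess(study.expression, study.metadata)
    de = run_diffexp(proc, study.metadata, RankProductConfig(seed=seed))
    planted = [g for g in de.index if study.truth.loc[g, "beta"] != 1]
    calls = de.loc[planted, "call"]
    sensitivity = float((calls == "up").mean())
    called = calls[calls != "not_significant"]
    direction_accuracy = float((called == "up").mean()) if len(called) else float("nan")
    return {
        "sensitivity": sensitivity,
        "direction_accuracy": direction_accuracy,
        "n_planted": len(planted),
        "n": len(de),
    }


# ---------------------------------------------------------------------------
# the dilution property
# ---------------------------------------------------------------------------

def dilution_property(seed: int = 0) -> dict:
    """Composition shift only (all beta = 1, leukocyte fraction means 0.05 vs
    0.30): apparent directions of the marker classes, wrong-direction
    significant calls, and the sample-graph MCL association with labour
    status vs null covariates."""
    catalog = default_catalog(
        class_sizes={"labour_induced": 0, "labour_repressed": 0}, seed=seed
    )
    study = generate_study(catalog, MixtureParams(), StudyDesign(seed=seed))
    proc, _ = preprocess(study.expression, study.metadata)
    de = run_diffexp(proc, study.metadata, RankProductConfig(seed=seed))
    cls = study.truth["gene_class"].reindex(de.index)
    muscle = de[cls == "muscle_specific"]
    leuk = de[cls == "leukocyte_specific"]
    return {
        "muscle_down_direction_pct": float((muscle["signed_fc"] < 0).mean() * 100),
        "leukocyte_up_direction_pct": float((leuk["signed_fc"] > 0).mean() * 100),
        "muscle_wrong_direction_calls": int((muscle["call"] == "up").sum()),
        "leukocyte_wrong_direction_calls": int((leuk["call"] == "down").sum()),
        "n_muscle": len(muscle),
        "n_leukocyte": len(leuk),
        "n": len(de),
    }


def sample_clustering_association(seed: int = 0) -> dict:
    """Sample-graph MCL clustering on the default synthetic study
    (composition shift plus transcriptional effects): association of cluster
    membership with labour status, and with null covariates (parity, BMI
    band), using the top up/down rank-product probes as graph input."""
    from .network import MODE_SAMPLE, cluster_trait_association

    catalog = default_catalog(seed=seed)
    study = generate_study(catalog, MixtureParams(), StudyDesign(seed=seed))
    proc, _ = preprocess(study.expression, study.metadata)
    de = run_diffexp(proc, study.metadata, RankProductConfig(seed=seed))
    selected = de["rp_up"].nsmallest(100).index.union(de["rp_down"].nsmallest(100).index)
    logged = np.log2(proc.subset_probes(selected).values)
    graph = correlation_graph(logged, MODE_SAMPLE, 0.85)
    assignment = mcl_cluster(graph, MCLConfig(inflation=3.0))
    md = study.metadata
    labour_p = cluster_trait_association(assignment, md, md["group"])["pvalue"]
    parity_p = cluster_trait_association(
        assignment, md, (md["parity"] > 0).map({True: "multi", False: "nulli"})
    )["pvalue"]
    bmi_p = cluster_trait_association(
        assignment, md, (md["bmi"] >= 30).map({True: "high", False: "normal"})
    )["pvalue"]
    return {
        "labour_association_p": float(labour_p),
        "parity_p": float(parity_p),
        "bmi_p": float(bmi_p),
        "n_clusters": assignment.n_clusters,
        "n_graph_probes": len(selected),
        "n": len(md),
    }


# ---------------------------------------------------------------------------
# MCL planted partition
# ---------------------------------------------------------------------------

def mcl_planted_partition(seed: int = 0) -> dict:
    """Adjusted Rand index of MCL (inflation 2.2) against a planted 3-block
    correlation structure, and cluster counts across inflation values."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(3):
        shared = rng.normal(size=60)
        for _ in range(8):
            rows.append(3.0 * shared + rng.normal(size=60))
            truth.append(b)
    vals = np.array(rows)
    graph = correlation_graph(_wrap(vals), MODE_PROBE, 0.5)
    labels = mcl_cluster(graph, MCLConfig(inflation=2.2)).labels
    truth = np.array(truth)
    pred = labels[[f"p{i}" for i in range(len(truth))]].to_numpy()

    # adjusted Rand index, computed directly from the contingency table
    def comb2(x):
        return x * (x - 1) / 2.0

    tab = pd.crosstab(truth, pred).to_numpy()
    sum_ij = comb2(tab).sum()
    a = comb2(tab.sum(axis=1)).sum()
    b = comb2(tab.sum(axis=0)).sum()
    n = comb2(len(truth))
    expected = a * b / n
    ari = (sum_ij - expected) / ((a + b) / 2 - expected)

    counts = [
        mcl_cluster(graph, MCLConfig(inflation=i)).n_clusters for i in (1.5, 2.2, 3.0, 4.0)
    ]
    return {
        "ari": float(ari),
        "cluster_counts_by_inflation": counts,
        "inflation_monotone": bool(counts == sorted(counts)),
        "n": len(truth),
    }


# ---------------------------------------------------------------------------
# Fisher exact vs enumeration
# ---------------------------------------------------------------------------

def fisher_enumeration_error(max_n: int = 30) -> dict:
    """Largest absolute deviation between the package's Fisher exact p-value
    and exhaustive rational-arithmetic enumeration over every 2×2 table with
    N ≤ max_n and positive margins."""
    from fractions import Fraction

    worst = 0.0
    checked = 0
    for n in range(2, max_n + 1):
        for a in range(n + 1):
            for bb in range(n - a + 1):
                for c in range(n - a - bb + 1):
                    d = n - a - bb - c
                    r1, r2 = a + bb, c + d
                    c1 = a + c
                    if r1 == 0 or r2 == 0 or c1 == 0 or (bb + d) == 0:
                        continue
                    denom = math.comb(n, c1)
                    probs = [
                        Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
                        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                    ]
                    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
                    oracle = float(sum(p for p in probs if p <= p_obs))
                    got = fisher_exact_2x2([[a, bb], [c, d]])
                    worst = max(worst, abs(got - oracle))
                    checked += 1
    return {"max_abs_error": worst, "n": checked}


# ---------------------------------------------------------------------------
# meta-analysis recovery
# ---------------------------------------------------------------------------

def meta_recovery(seed: int = 0, n_replicates: int = 200, true_smd: float = 0.8) -> dict:
    """Three simulated two-group studies (n=20+20) per replicate with a true
    standardized mean difference of 0.8: bias of the fixed-effect pooled
    estimate and empirical 95% CI coverage."""
    rng = np.random.default_rng(seed)
    estimates, covered = [], 0
    for _ in range(n_replicates):
        recs = []
        for s in range(3):
            x_l = rng.normal(true_smd, 1.0, size=20)
            x_nl = rng.normal(0.0, 1.0, size=20)
            recs.append(
                smd(
                    float(x_l.mean()), float(x_nl.mean()),
                    float(x_l.std(ddof=1)), float(x_nl.std(ddof=1)),
                    20, 20, study=f"s{s}", gene="G",
                )
            )
        m = pool(recs)
        estimates.append(m.pooled_fixed[0])
        lo, hi = m.pooled_fixed[2]
        covered += lo <= true_smd <= hi
    return {
        "mean_estimate": float(np.mean(estimates)),
        "true_smd": true_smd,
        "ci_coverage_pct": 100.0 * covered / n_replicates,
        "n": n_replicates,
    }


def meta_hand_fixture() -> dict:
    """The two-study inverse-variance fixture with known closed-form answer."""
    recs = [SMDRecord("a", "G", 0.5, 0.5, 0.1), SMDRecord("b", "G", 1.0, 1.0, 0.2)]
    m = pool(recs)
    return {
        "fixed_estimate": m.pooled_fixed[0],
        "fixed_se": m.pooled_fixed[1],
        "Q": m.Q,
        "tau2": m.tau2,
        "n": 2,
    }


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_null_flag(seed: int = 0) -> dict:
    """Excluding the effect-free induced/augmented subgroup: fold-change
    stability statistics."""
    catalog = default_catalog(
        class_sizes={"labour_induced": 0, "labour_repressed": 0}, seed=seed
    )
    study = generate_study(catalog, MixtureParams(), StudyDesign(seed=seed))
    proc, _ = preprocess(study.expression, study.metadata)
    rep = subgroup_sensitivity(proc, study.metadata, "induction")
    return {
        "median_abs_diff": rep.median_abs_diff,
        "pearson_r": rep.pearson_r,
        "pct_same_direction": rep.pct_same_direction,
        "iqr_low": rep.iqr_signed_diff[0],
        "iqr_high": rep.iqr_signed_diff[1],
        "n": rep.n_probes,
    }
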