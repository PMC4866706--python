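"""Cross-study standardized-mean-difference meta-analysis and concordance.

Studies are harmonized to their common gene set (probes collapsed to genes
by highest mean intensity), per-gene effects are expressed as Hedges' g —
the pooled-SD standardized mean difference with the small-sample bias
correction J = 1 − 3/(4·df − 1), material at the 6–26 samples-per-group
sizes typical of myometrial array studies — and pooled by inverse-variance
weighting.  Fixed-effect and DerSimonian–Laird random-effects estimates are
both reported, alongside Cochran's Q, its chi-squared tail probability and
tau², since either pooling model may be preferred depending on observed
heterogeneity.  Cross-study concordance of differential-expression calls is
summarized per study pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, group_samples
from .diffexp import CALL_NS


@dataclass(frozen=True)
class SMDRecord:
    """One study × gene effect: Cohen's d, Hedges' g and its variance."""

    study: str
    gene: str
    d: float
    g: float
    var_g: float

    def __post_init__(self) -> None:
        if not self.var_g > 0:
            raise ValueError(f"var_g must be > 0, got {self.var_g}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one gene with heterogeneity statistics."""

    gene: str
    k: int
    pooled_fixed: tuple[float, float, tuple[float, float]]  # (estimate, SE, CI)
    pooled_random: tuple[float, float, tuple[float, float]]
    Q: float
    df: int
    p_Q: float
    tau2: float


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def collapse_probes_to_genes(
    matrix: ExpressionMatrix, rule: str = "max_mean"
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level using its annotation.

    ``max_mean`` (default): the probe with the highest mean intensity across
    the study's samples represents the gene; ``mean``: average all probes.
    """
    if matrix.annotation is None or "gene_symbol" not in matrix.annotation:
        raise ValueError("collapse requires a gene_symbol annotation")
    values = matrix.regular()
    symbols = matrix.annotation.loc[values.index, "gene_symbol"]
    if rule == "mean":
        return values.groupby(symbols).mean()
    if rule != "max_mean":
        raise ValueError(f"unknown collapse rule {rule!r}")
    means = values.mean(axis=1)
    best = means.groupby(symbols).idxmax()
    collapsed = values.loc[best]
    collapsed.index = best.index
    return collapsed.sort_index()


def harmonize_genes(
    studies: list[ExpressionMatrix], rule: str = "max_mean"
) -> list[pd.DataFrame]:
    """Restrict every study to the genes covered by all platforms.

    Returns gene-by-sample matrices indexed identically; raises (naming the
    smallest contributor) when the intersection is empty.
    """
    if len(studies) < 2:
        raise ValueError("harmonize_genes needs >= 2 studies")
    collapsed = [collapse_probes_to_genes(s, rule=rule) for s in studies]
    common: set = set(collapsed[0].index)
    for c in collapsed[1:]:
        common &= set(c.index)
    if not common:
        sizes = [len(c.index) for c in collapsed]
        smallest = int(np.argmin(sizes))
        raise ValueError(
            f"empty gene intersection; smallest contributor is study {smallest} "
            f"with {sizes[smallest]} genes"
        )
    genes = sorted(common)
    return [c.loc[genes] for c in collapsed]


def study_summary(
    gene_matrix: pd.DataFrame, metadata: pd.DataFrame, study: str, log2: bool = True
) -> pd.DataFrame:
    """Per-gene group means/SDs/ns for one study (log2 scale by default,
    where within-group distributions are roughly symmetric)."""
    lab, non = group_samples(metadata)
    x = np.log2(gene_matrix) if log2 else gene_matrix
    return pd.DataFrame(
        {
            "study": study,
            "mean_L": x[lab].mean(axis=1),
            "mean_NL": x[non].mean(axis=1),
            "sd_L": x[lab].std(axis=1, ddof=1),
            "sd_NL": x[non].std(axis=1, ddof=1),
            "n_L": len(lab),
            "n_NL": len(non),
        }
    )


# ---------------------------------------------------------------------------
# effect sizes and pooling
# ---------------------------------------------------------------------------

def smd(
    mean_l: float,
    mean_nl: float,
    sd_l: float,
    sd_nl: float,
    n_l: int,
    n_nl: int,
    study: str = "",
    gene: str = "",
) -> SMDRecord:
    """Hedges-corrected standardized mean difference for one study × gene.

    d = (mean_L − mean_NL) / s_p with the pooled SD; g = J·d with
    J = 1 − 3/(4(n_L+n_NL−2) − 1); var_g = (n_L+n_NL)/(n_L·n_NL) +
    g²/(2(n_L+n_NL)).
    """
    if n_l < 2 or n_nl < 2:
        raise ValueError("smd needs >= 2 samples per group")
    df = n_l + n_nl - 2
    s_p = np.sqrt(((n_l - 1) * sd_l**2 + (n_nl - 1) * sd_nl**2) / df)
    if s_p == 0:
        raise ValueError(f"degenerate gene {gene!r}: pooled SD is zero")
    d = (mean_l - mean_nl) / s_p
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    n = n_l + n_nl
    var_g = n / (n_l * n_nl) + g**2 / (2.0 * n)
    return SMDRecord(study=study, gene=gene, d=float(d), g=float(g), var_g=float(var_g))


def smd_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`smd` over a study-summary table; genes with zero
    pooled SD are dropped with a warning."""
    out = []
    for gene, row in summary.iterrows():
        try:
            rec = smd(
                row["mean_L"], row["mean_NL"], row["sd_L"], row["sd_NL"],
                int(row["n_L"]), int(row["n_NL"]), study=str(row["study"]), gene=str(gene),
            )
        except ValueError:
            warnings.warn(f"skipping degenerate gene {gene!r} (zero pooled SD)")
            continue
        out.append({"study": rec.study, "gene": rec.gene, "d": rec.d, "g": rec.g, "var_g": rec.var_g})
    return pd.DataFrame(out)


def pool(records: list[SMDRecord], gene: str | None = None) -> MetaResult:
    """Inverse-variance pooling of one gene's study effects.

    Fixed effect: w_i = 1/var_i.  Heterogeneity: Cochran's Q against the
    fixed estimate, df = k−1, tau² = max(0, (Q−df)/C) with
    C = Σw − Σw²/Σw (DerSimonian–Laird).  Random effects reuse the same
    machinery with w*_i = 1/(var_i + tau²).  95% CIs are estimate ± 1.96·SE.
    A single study passes through unchanged with Q = 0, tau² = 0.
    """
    if not records:
        raise ValueError("pool needs at least one SMD record")
    gene = gene if gene is not None else records[0].gene
    g = np.array([r.g for r in records], float)
    v = np.array([r.var_g for r in records], float)
    k = len(records)
    w = 1.0 / v
    est_f = float(np.sum(w * g) / np.sum(w))
    se_f = float(1.0 / np.sqrt(np.sum(w)))
    if k == 1:
        q, p_q, tau2 = 0.0, 1.0, 0.0
        est_r, se_r = est_f, se_f
    else:
        q = float(np.sum(w * (g - est_f) ** 2))
        df = k - 1
        p_q = float(stats.chi2.sf(q, df))
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (v + tau2)
        est_r = float(np.sum(w_star * g) / np.sum(w_star))
        se_r = float(1.0 / np.sqrt(np.sum(w_star)))
    ci_f = (est_f - 1.96 * se_f, est_f + 1.96 * se_f)
    ci_r = (est_r - 1.96 * se_r, est_r + 1.96 * se_r)
    return MetaResult(
        gene=gene,
        k=k,
        pooled_fixed=(est_f, se_f, ci_f),
        pooled_random=(est_r, se_r, ci_r),
        Q=q,
        df=k - 1,
        p_Q=p_q if k > 1 else 1.0,
        tau2=tau2,
    )


def pool_all(smds: pd.DataFrame) -> pd.DataFrame:
    """Pool every gene present in an SMD long table; one row per gene."""
    rows = []
    for gene, sub in smds.groupby("gene", sort=True):
        recs = [
            SMDRecord(study=r["study"], gene=gene, d=r["d"], g=r["g"], var_g=r["var_g"])
            for _, r in sub.iterrows()
        ]
        m = pool(recs, gene=gene)
        rows.append(
            {
                "gene": gene,
                "k": m.k,
                "pooled_fixed": m.pooled_fixed[0],
                "se_fixed": m.pooled_fixed[1],
                "ci_low_fixed": m.pooled_fixed[2][0],
                "ci_high_fixed": m.pooled_fixed[2][1],
                "pooled_random": m.pooled_random[0],
                "se_random": m.pooled_random[1],
                "ci_low_random": m.pooled_random[2][0],
                "ci_high_random": m.pooled_random[2][1],
                "Q": m.Q,
                "df": m.df,
                "p_Q": m.p_Q,
                "tau2": m.tau2,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def de_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    shared: list[str] | set[str],
) -> dict:
    """Cross-study concordance of DE calls over a shared gene set.

    Percentages (in [0, 100]) are: A's significant genes replicated in B
    (significant, same fc sign); A's significant genes with the same fc sign
    in B regardless of B's significance; genes significant in both with
    opposite signs.  Undefined percentages (A has no significant genes) are
    reported as NaN with a warning.
    """
    shared = sorted(set(shared) & set(results_a.index) & set(results_b.index))
    a = results_a.loc[shared]
    b = results_b.loc[shared]
    sig_a = a["call"] != CALL_NS
    sig_b = b["call"] != CALL_NS
    same_sign = np.sign(a["signed_fc"]) == np.sign(b["signed_fc"])
    n_sig_a = int(sig_a.sum())
    both_sig = sig_a & sig_b
    report = {
        "n_shared_genes": len(shared),
        "n_sig_A": n_sig_a,
        "n_sig_B": int(sig_b.sum()),
    }
    if n_sig_a == 0:
        warnings.warn("study A has no significant genes; concordance undefined")
        report.update(
            pct_sig_replicated_same_direction=float("nan"),
            pct_same_direction_all=float("nan"),
            pct_direction_conflict_among_sig=float("nan"),
        )
        return report
    report["pct_sig_replicated_same_direction"] = 100.0 * float(
        (both_sig & same_sign).sum() / n_sig_a
    )
    report["pct_same_direction_all"] = 100.0 * float((sig_a & same_sign).sum() / n_sig_a)
    n_both = int(both_sig.sum())
    report["pct_direction_conflict_among_sig"] = (
        100.0 * float((both_sig & ~same_sign).sum() / n_both) if n_both else 0.0
    )
    return report
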