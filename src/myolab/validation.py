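"""Internal-consistency procedures: subgroup sensitivity analysis,
qRT-PCR delta-CT comparison and cross-platform log-ratio concordance.

The sensitivity analysis re-derives signed fold changes after excluding a
flagged subgroup (e.g. women whose labour was pharmacologically induced or
augmented) and summarizes how far the fold-change vector moved; a null flag
should leave the vector essentially unchanged.  The delta-CT comparison is
the standard qRT-PCR contract: dCT = CT(target) − CT(reference), two-sample
t-test between groups, remembering that *lower* dCT means *higher*
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, check_metadata, group_samples
from .diffexp import RankProductConfig, signed_fold_change


@dataclass(frozen=True)
class SensitivityReport:
    """How far the fold-change vector moved when a subgroup was excluded."""

    n_probes: int
    median_abs_diff: float
    iqr_signed_diff: tuple[float, float]
    pearson_r: float
    pct_same_direction: float


@dataclass(frozen=True)
class DeltaCtResult:
    """Two-group comparison of one gene's delta-CT values."""

    gene: str
    mean_dct_L: float
    mean_dct_NL: float
    t_stat: float
    pvalue: float
    direction_call: str  # expression direction in labour (inverse of dCT)


def _signed_fc_vector(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.Series:
    lab, non = group_samples(metadata)
    mean_l = matrix.values[lab].mean(axis=1)
    mean_nl = matrix.values[non].mean(axis=1)
    return pd.Series(
        signed_fold_change(mean_l.to_numpy(), mean_nl.to_numpy()), index=matrix.probe_ids
    )


def subgroup_sensitivity(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    exclude_flag: str | pd.Series,
    de_cfg: RankProductConfig | None = None,
) -> SensitivityReport:
    """Compare signed fold changes with and without a flagged subgroup.

    ``exclude_flag`` is either a metadata column (samples with values other
    than 'none'/False are dropped) or a boolean Series.  Differences are
    computed on the signed-fold-change scale; the IQR is of *signed*
    differences (it straddles zero when the exclusion is null).
    """
    md = check_metadata(metadata)
    if isinstance(exclude_flag, str):
        col = md[exclude_flag]
        if col.dtype == bool:
            excluded = col
        else:  # categorical flag: 'none'-like values mean not flagged
            excluded = ~col.astype(str).str.lower().isin({"none", "", "nan", "false", "0"})
    else:
        excluded = exclude_flag.reindex(md.index).fillna(False).astype(bool)
    keep = list(md.index[~excluded])
    kept_md = md.loc[keep]
    lab, non = group_samples(kept_md)
    if len(lab) < 2 or len(non) < 2:
        raise ValueError("exclusion leaves fewer than 2 samples in a group")

    fc_full = _signed_fc_vector(matrix, md)
    fc_sub = _signed_fc_vector(matrix.subset_samples(keep), kept_md)
    diff = (fc_sub - fc_full).to_numpy()
    q1, q3 = np.percentile(diff, [25, 75])
    if np.allclose(fc_full, fc_sub):
        r = 1.0
    else:
        r = float(np.corrcoef(fc_full, fc_sub)[0, 1])
    same = float(np.mean(np.sign(fc_full) == np.sign(fc_sub)) * 100.0)
    return SensitivityReport(
        n_probes=len(fc_full),
        median_abs_diff=float(np.median(np.abs(diff))),
        iqr_signed_diff=(float(q1), float(q3)),
        pearson_r=r,
        pct_same_direction=same,
    )


def delta_ct_compare(
    ct_table: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_gene: str = "18S",
    welch: bool = False,
) -> tuple[list[DeltaCtResult], pd.Series]:
    """Two-group t-tests on delta-CT values for every target gene.

    ``ct_table`` holds raw CT values, one row per gene (including the
    reference) and one column per sample.  dCT = CT(target) − CT(reference);
    the pooled-variance Student t-test is the default (Welch optional).
    Samples missing any CT value are dropped with a warning.  Also returns
    the group means of the raw reference-gene CT (the reference-stability
    check).
    """
    md = check_metadata(metadata)
    if reference_gene not in ct_table.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from CT table")
    common = [s for s in ct_table.columns if s in md.index]
    ct = ct_table[common]
    complete = ct.notna().all(axis=0)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} samples with missing CT values")
    ct = ct.loc[:, complete]
    if ct.shape[1] == 0:
        raise ValueError("no samples with complete CT data")
    md = md.loc[ct.columns]
    lab, non = group_samples(md)
    if len(lab) < 2 or len(non) < 2:
        raise ValueError("delta_ct_compare needs >= 2 complete samples per group")

    ref = ct.loc[reference_gene]
    ref_group_means = pd.Series(
        {"labour": float(ref[lab].mean()), "nonlabour": float(ref[non].mean())},
        name=f"mean_raw_CT_{reference_gene}",
    )
    results = []
    for gene in ct.index:
        if gene == reference_gene:
            continue
        dct = ct.loc[gene] - ref
        a, b = dct[lab].to_numpy(float), dct[non].to_numpy(float)
        mean_diff = a.mean() - b.mean()
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            # degenerate constant samples: define t by the limit
            t = 0.0 if mean_diff == 0 else np.inf * np.sign(mean_diff)
            p = 1.0 if mean_diff == 0 else 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        direction = (
            "higher expression in labour" if mean_diff < 0 else
            "lower expression in labour" if mean_diff > 0 else "no difference"
        )
        results.append(
            DeltaCtResult(
                gene=gene,
                mean_dct_L=float(a.mean()),
                mean_dct_NL=float(b.mean()),
                t_stat=float(t),
                pvalue=float(p),
                direction_call=direction,
            )
        )
    return results, ref_group_means


def crossplatform_concordance(
    log_ratios_a: pd.Series, log_ratios_b: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Pearson r between two platforms' per-gene log2 group ratios plus a
    per-gene sign-agreement table (≥3 shared genes required)."""
    shared = sorted(set(log_ratios_a.index) & set(log_ratios_b.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, have {len(shared)}")
    a = log_ratios_a.loc[shared].to_numpy(float)
    b = log_ratios_b.loc[shared].to_numpy(float)
    r = float(np.corrcoef(a, b)[0, 1])
    table = pd.DataFrame(
        {
            "log2_ratio_A": a,
            "log2_ratio_B": b,
            "same_direction": np.sign(a) == np.sign(b),
        },
        index=pd.Index(shared, name="gene"),
    )
    return r, table
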