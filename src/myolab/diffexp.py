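"""Rank-product differential expression with permutation PFP correction.

The rank product is a non-parametric two-group statistic: over many pairwise
labouring-vs-non-labouring sample comparisons, each probe's fold-change rank
is recorded and the statistic is the geometric mean of those ranks.  A probe
consistently near the top of every comparison gets a rank product near 1.
Significance is expressed as the percentage of false positives (PFP): a
permutation null supplies the distribution of rank products expected without
any group effect, the expected number of null probes beating each observed
value is computed, and dividing by the probe's rank among observed values
gives an FDR-like quantity that is thresholded (conventionally at 0.05)
together with a fold-change cutoff (conventionally 1.2) to call differential
expression.

The null permutes each probe's intensities across samples while keeping the
pairwise-comparison structure fixed.  Because the comparisons are all
labour × non-labour sample pairs, a probe's ranks are correlated across
comparisons that share a sample; permuting within comparisons independently
would ignore that dependence and grossly understate the spread of null rank
products, so the sample-level permutation — exact under within-probe
exchangeability — is the one used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, group_samples

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "not_significant"


@dataclass(frozen=True)
class RankProductConfig:
    """Tuning for the rank-product test.

    ``max_pairs`` caps the number of pairwise comparisons (all nL × nNL pairs
    are used when they fit, otherwise a seeded random subset); ``scale``
    selects whether per-pair ratios are formed on the normalized raw scale
    (default, consistent with the non-log fold-change convention) or as log2
    differences — the ranks, hence the statistic, agree on both scales.
    """

    n_permutations: int = 100
    max_pairs: int = 100
    seed: int = 0
    scale: str = "raw"
    fc_threshold: float = 1.2
    pfp_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 10:
            raise ValueError(f"n_permutations must be >= 10, got {self.n_permutations}")
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.fc_threshold <= 0 or self.pfp_alpha <= 0:
            raise ValueError("fc_threshold and pfp_alpha must be positive")


def signed_fold_change(mean_l, mean_nl):
    """Signed ratio of group means: +R when higher in labour, −1/R when
    lower, magnitude always ≥ 1.  Accepts scalars or arrays."""
    mean_l = np.asarray(mean_l, dtype=float)
    mean_nl = np.asarray(mean_nl, dtype=float)
    if np.any(mean_l <= 0) or np.any(mean_nl <= 0):
        raise ValueError("signed_fold_change requires strictly positive group means")
    r = mean_l / mean_nl
    out = np.where(r >= 1, r, -1.0 / r)
    return float(out) if out.ndim == 0 else out


def _pair_indices(
    n_l: int, n_nl: int, max_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """(K, 2) array of (labour index, non-labour index) comparisons."""
    all_pairs = np.array([(i, j) for i in range(n_l) for j in range(n_nl)])
    if len(all_pairs) <= max_pairs:
        return all_pairs
    pick = rng.choice(len(all_pairs), size=max_pairs, replace=False)
    return all_pairs[np.sort(pick)]


def _pairwise_ranks(
    x_l: np.ndarray, x_nl: np.ndarray, pairs: np.ndarray, scale: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-comparison up/down ranks, shape (G, K).

    Rank 1 = most up-regulated (largest labour/non-labour ratio) for the up
    ranks; ascending for down; ties averaged.  With average ties the two
    rankings are exact reverses: up = G + 1 − down.
    """
    if scale == "log2":
        ratios = x_l[:, pairs[:, 0]] - x_nl[:, pairs[:, 1]]
    else:
        ratios = x_l[:, pairs[:, 0]] / x_nl[:, pairs[:, 1]]
    down = rankdata(ratios, method="average", axis=0)
    up = ratios.shape[0] + 1 - down
    return up, down


def _geometric_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    """Geometric mean over comparisons, accumulated in log space."""
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    cfg: RankProductConfig,
) -> pd.DataFrame:
    """Per-probe rank products; columns ``rp_up`` and ``rp_down``."""
    lab, non = group_samples(metadata)
    if len(lab) < 2 or len(non) < 2:
        raise ValueError("rank_product needs >= 2 samples per group")
    X = matrix.values
    x_l = X[lab].to_numpy(float)
    x_nl = X[non].to_numpy(float)
    if cfg.scale == "log2":
        x_l, x_nl = np.log2(x_l), np.log2(x_nl)
    rng = np.random.default_rng(cfg.seed)
    pairs = _pair_indices(len(lab), len(non), cfg.max_pairs, rng)
    if len(pairs) < 1:
        raise ValueError("rank_product needs at least one pairwise comparison")
    up, down = _pairwise_ranks(x_l, x_nl, pairs, cfg.scale)
    return pd.DataFrame(
        {"rp_up": _geometric_mean_ranks(up), "rp_down": _geometric_mean_ranks(down)},
        index=matrix.probe_ids,
    )


def permutation_null(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    cfg: RankProductConfig,
) -> np.ndarray:
    """(B, G) null rank products.

    Each permutation shuffles every probe's intensity vector across all
    samples independently (within-probe exchangeability under the null) and
    recomputes the rank products through the identical pairwise-comparison
    structure, preserving the rank dependence induced by shared samples.
    The up and down null distributions coincide by symmetry, so one sample
    serves both directions.  Deterministic given ``cfg.seed``.
    """
    lab, non = group_samples(metadata)
    X = matrix.values
    x = np.concatenate(
        [X[lab].to_numpy(float), X[non].to_numpy(float)], axis=1
    )
    if cfg.scale == "log2":
        x = np.log2(x)
    n_l = len(lab)
    rng = np.random.default_rng(cfg.seed)
    pairs = _pair_indices(n_l, len(non), cfg.max_pairs, rng)
    null_rng = np.random.default_rng(cfg.seed + 1)
    g = x.shape[0]
    null = np.empty((cfg.n_permutations, g))
    for b in range(cfg.n_permutations):
        xp = null_rng.permuted(x, axis=1)
        up, _ = _pairwise_ranks(xp[:, :n_l], xp[:, n_l:], pairs, "log2" if cfg.scale == "log2" else "raw")
        null[b] = _geometric_mean_ranks(up)
    return null


def estimate_pfp(
    observed_rp: pd.Series,
    matrix: ExpressionMatrix | None = None,
    metadata: pd.DataFrame | None = None,
    cfg: RankProductConfig | None = None,
    null_rp: np.ndarray | None = None,
) -> pd.DataFrame:
    """Permutation PFP and p-values for one direction's rank products.

    For each probe: ``c`` = count of null rank products ≤ its observed value
    over B permutations; expected false positives E = c/B; PFP = E / (probe's
    ascending rank among observed values); p = c/(B·G).  PFP is then made
    monotone non-decreasing in the rank product (running maximum), so
    threshold sets are nested in alpha.  Deterministic given ``cfg.seed``.

    Pass ``null_rp`` to reuse a precomputed null (e.g. for both directions);
    otherwise the null is generated from ``matrix``/``metadata``.
    """
    cfg = cfg or RankProductConfig()
    if cfg.n_permutations < 10:
        raise ValueError("PFP estimate needs >= 10 permutations")
    if null_rp is None:
        if matrix is None or metadata is None:
            raise ValueError("estimate_pfp needs either null_rp or matrix+metadata")
        null_rp = permutation_null(matrix, metadata, cfg)
    g = len(observed_rp)
    obs = observed_rp.to_numpy(float)
    b = null_rp.shape[0]
    flat = np.sort(null_rp.ravel())
    c = np.searchsorted(flat, obs, side="right")
    expected = c / b
    rho = rankdata(obs, method="average")
    pfp = expected / rho
    pvalue = c / (b * g)
    # running maximum over ascending rank-product order
    order = np.argsort(obs, kind="stable")
    pfp_sorted = np.maximum.accumulate(pfp[order])
    pfp_mono = np.empty_like(pfp)
    pfp_mono[order] = pfp_sorted
    return pd.DataFrame(
        {"pfp": pfp_mono, "pvalue": pvalue, "expected_fp": expected},
        index=observed_rp.index,
    )


def select_differential(results: pd.DataFrame, cfg: RankProductConfig) -> tuple[list, list]:
    """Split a DE table into (up, down) probe lists.

    up: ``pfp_up ≤ alpha`` and ``signed_fc ≥ +fc_threshold``; down mirrored.
    A probe qualifying in both directions goes to the direction with the
    smaller PFP (exact tie → the fc sign, which cannot favour both sides,
    decides).
    """
    up_mask = (results["pfp_up"] <= cfg.pfp_alpha) & (
        results["signed_fc"] >= cfg.fc_threshold
    )
    down_mask = (results["pfp_down"] <= cfg.pfp_alpha) & (
        results["signed_fc"] <= -cfg.fc_threshold
    )
    both = up_mask & down_mask
    up_wins = results["pfp_up"] < results["pfp_down"]
    down_wins = results["pfp_down"] < results["pfp_up"]
    up_final = up_mask & (~both | up_wins)
    down_final = down_mask & (~both | down_wins)
    tied = both & ~up_wins & ~down_wins
    if tied.any():
        sign_up = results["signed_fc"] > 0
        up_final |= tied & sign_up
        down_final |= tied & ~sign_up
        warnings.warn(f"{int(tied.sum())} probes tied between up/down; resolved by fc sign")
    return list(results.index[up_final]), list(results.index[down_final])


def run_diffexp(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    cfg: RankProductConfig | None = None,
) -> pd.DataFrame:
    """Full DE stage: fold changes, rank products, PFP in both directions
    and the up/down/not_significant call per probe."""
    cfg = cfg or RankProductConfig()
    lab, non = group_samples(metadata)
    X = matrix.values
    mean_l = X[lab].mean(axis=1)
    mean_nl = X[non].mean(axis=1)
    fc = signed_fold_change(mean_l.to_numpy(), mean_nl.to_numpy())

    rp = rank_product(matrix, metadata, cfg)
    null = permutation_null(matrix, metadata, cfg)
    pfp_up = estimate_pfp(rp["rp_up"], cfg=cfg, null_rp=null)
    pfp_down = estimate_pfp(rp["rp_down"], cfg=cfg, null_rp=null)

    result = pd.DataFrame(
        {
            "mean_L": mean_l,
            "mean_NL": mean_nl,
            "signed_fc": fc,
            "rp_up": rp["rp_up"],
            "rp_down": rp["rp_down"],
            "pfp_up": pfp_up["pfp"],
            "pfp_down": pfp_down["pfp"],
            "pvalue_up": pfp_up["pvalue"],
            "pvalue_down": pfp_down["pvalue"],
        },
        index=matrix.probe_ids,
    )
    if matrix.annotation is not None and "gene_symbol" in matrix.annotation:
        result.insert(0, "gene_symbol", matrix.annotation["gene_symbol"])
    up, down = select_differential(result, cfg)
    call = pd.Series(CALL_NS, index=result.index, dtype=object)
    call.loc[up] = CALL_UP
    call.loc[down] = CALL_DOWN
    result["call"] = call
    return result
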