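"""Intensity-matrix preprocessing: background correction, quantile
normalization and detection-floor filtering.

Background correction follows the normal+exponential convolution model that
underlies RMA-style correction: the observed intensity is O = B + S with
B ~ Normal(mu, sigma^2) background and S ~ Exponential(theta) signal, and
each observation is replaced by the posterior mean E[S | O = o] with the
background constrained positive (so S is a Normal(a, sigma^2) truncated to
(0, o), a = o - mu - sigma^2/theta).  Per-sample parameters are estimated
from the negative-control probes, which is the natural estimator on bead
arrays where every chip carries a dedicated negative-control set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import ExpressionMatrix, check_metadata, group_samples

logger = logging.getLogger(__name__)

#: lower bound used for degenerate scale parameters
EPSILON = 1e-6


@dataclass(frozen=True)
class NormexpParams:
    """Normal+exponential convolution parameters for one sample."""

    mu: float
    sigma: float
    theta: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")


def estimate_normexp_params(matrix: ExpressionMatrix, sample: str) -> NormexpParams:
    """Estimate per-sample background/signal parameters from the
    negative-control probes.

    ``mu``/``sigma`` are the mean and SD of the sample's control intensities;
    ``theta`` is the mean regular-probe excess over background, floored at a
    small positive constant.
    """
    controls = matrix.controls()[sample].to_numpy(float)
    if controls.size < 10:
        raise ValueError(
            f"normexp estimation needs >= 10 negative-control probes, have {controls.size}"
        )
    mu = float(np.mean(controls))
    sigma = float(np.std(controls, ddof=1))
    if sigma <= 0:
        logger.warning("zero variance among control probes for %s; sigma floored", sample)
        sigma = EPSILON
    theta = max(float(np.mean(matrix.regular()[sample].to_numpy(float))) - mu, EPSILON)
    return NormexpParams(mu=mu, sigma=sigma, theta=theta)


def _truncnorm_mean(a: np.ndarray, sigma: float, upper: np.ndarray) -> np.ndarray:
    """Mean of Normal(a, sigma^2) truncated to (0, upper), computed stably.

    Uses the scaled complementary error function so both far tails stay
    finite; equivalent to a log-space evaluation of the phi/Phi ratio.
    """
    # standardized bounds
    alpha = (0.0 - a) / sigma
    beta = (upper - a) / sigma
    # E = a + sigma * (phi(alpha) - phi(beta)) / (Phi(beta) - Phi(alpha))
    sqrt2 = np.sqrt(2.0)
    # Phi(beta) - Phi(alpha) = 0.5*(erf(beta/sqrt2) - erf(alpha/sqrt2))
    denom = 0.5 * (special.erf(beta / sqrt2) - special.erf(alpha / sqrt2))
    phi_a = np.exp(-0.5 * alpha**2) / np.sqrt(2 * np.pi)
    phi_b = np.exp(-0.5 * beta**2) / np.sqrt(2 * np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = a + sigma * (phi_a - phi_b) / denom
    # Far-tail fallback: when the mass in (0, upper) underflows, the posterior
    # concentrates at the nearer boundary of the interval.
    bad = ~np.isfinite(mean) | (denom <= 0)
    if np.any(bad):
        # a << 0: mass piles just above 0 -> inverse-Mills asymptotic sigma/|alpha|
        lo = bad & (a < 0)
        with np.errstate(divide="ignore"):
            mean = np.where(lo, sigma / np.maximum(alpha, 1.0), mean)
        # a >> upper: mass piles just below upper
        hi = bad & (a >= 0)
        mean = np.where(hi, np.minimum(a, upper) - sigma**2 / np.maximum(a, sigma), mean)
    return mean


def normexp_correct(
    matrix: ExpressionMatrix, params: dict[str, NormexpParams] | None = None
) -> ExpressionMatrix:
    """Background-correct every sample by the normexp posterior mean.

    Output intensities are strictly positive and monotone increasing in the
    input for fixed parameters.  Parameters default to per-sample estimates
    from the negative controls.
    """
    if params is None:
        params = {s: estimate_normexp_params(matrix, s) for s in matrix.sample_ids}
    missing = [s for s in matrix.sample_ids if s not in params]
    if missing:
        raise ValueError(f"normexp params missing for samples: {missing}")
    corrected = {}
    for s in matrix.sample_ids:
        p = params[s]
        o = matrix.values[s].to_numpy(float)
        a = o - p.mu - p.sigma**2 / p.theta
        vals = _truncnorm_mean(a, p.sigma, o)
        corrected[s] = np.maximum(vals, EPSILON)  # contract: never <= 0
    out = pd.DataFrame(corrected, index=matrix.probe_ids)[list(matrix.sample_ids)]
    return matrix.with_values(out)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common rank-mean reference distribution.

    The reference value at rank r is the mean across samples of each
    sample's rank-r intensity; within-sample ties receive the mean of the
    reference values over their tied rank span, which makes the operation
    idempotent and conserves the grand mean.
    """
    X = matrix.values.to_numpy(float)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single-sample matrix returned unchanged")
        return matrix.with_values(matrix.values.copy())
    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        sort_idx = order[:, j]
        sorted_col = col[sort_idx]
        # tie spans over the sorted column
        boundary = np.empty(n_probes, dtype=bool)
        boundary[0] = True
        boundary[1:] = sorted_col[1:] != sorted_col[:-1]
        span_id = np.cumsum(boundary) - 1
        starts = np.flatnonzero(boundary)
        ends = np.concatenate([starts[1:], [n_probes]])
        span_mean = (ref_cumsum[ends] - ref_cumsum[starts]) / (ends - starts)
        out[sort_idx, j] = span_mean[span_id]
    values = pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
    return matrix.with_values(values)


def compute_detection_floor(matrix: ExpressionMatrix) -> int:
    """Detection floor = median negative-control intensity over all samples,
    rounded to the nearest integer (halves away from zero)."""
    controls = matrix.controls().to_numpy(float).ravel()
    if controls.size == 0:
        raise ValueError(
            "no negative-control probes: supply an explicit floor to floor_filter"
        )
    med = float(np.median(controls))
    return int(np.sign(med) * np.floor(np.abs(med) + 0.5))


def floor_filter(
    matrix: ExpressionMatrix, metadata: pd.DataFrame, floor: float
) -> ExpressionMatrix:
    """Drop probes deemed unexpressed: retained iff at least one group's mean
    intensity reaches the floor.  Negative-control probes are always removed
    from the analysis matrix (they remain available on the input object)."""
    md = check_metadata(metadata)
    lab, non = group_samples(md)
    if not lab or not non:
        raise ValueError("floor_filter requires samples in both groups")
    regular = matrix.regular()
    mean_l = regular[lab].mean(axis=1)
    mean_n = regular[non].mean(axis=1)
    keep = (mean_l >= floor) | (mean_n >= floor)
    if not keep.any():
        raise ValueError("floor_filter removed every probe; floor too high?")
    return matrix.subset_probes(regular.index[keep])


def preprocess(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    floor: float | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Full chain: normexp correction → quantile normalization → floor filter.

    Returns the filtered analysis matrix plus a report dict (per-sample
    params, floor used, probe counts).  Deterministic: no randomness.
    """
    params = {s: estimate_normexp_params(matrix, s) for s in matrix.sample_ids}
    corrected = normexp_correct(matrix, params)
    normalized = quantile_normalize(corrected)
    used_floor = compute_detection_floor(matrix) if floor is None else floor
    filtered = floor_filter(normalized, metadata, used_floor)
    report = {
        "floor": float(used_floor),
        "floor_source": "negative_control_median" if floor is None else "override",
        "n_probes_input": int(matrix.n_probes),
        "n_control_probes": int(matrix.is_control.sum()),
        "n_probes_retained": int(filtered.n_probes),
        "n_probes_removed": int(matrix.n_probes - matrix.is_control.sum() - filtered.n_probes),
        "normexp_params": {
            s: {"mu": p.mu, "sigma": p.sigma, "theta": p.theta} for s, p in params.items()
        },
    }
    return filtered, report
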