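"""Correlation-network construction, Markov Clustering and cluster summaries.

Two graph modes mirror the two views of a two-group expression study: a
sample–sample graph (nodes = samples, edges = Pearson r between their
expression profiles over a probe set, conventionally thresholded at r > 0.85)
and a probe–probe graph (nodes = probes, edges = co-expression across
samples, r > 0.80).  Markov Clustering (MCL) alternates expansion (matrix
powering) and inflation (elementwise powering + column renormalization) of a
column-stochastic matrix until it reaches an attractor structure whose
connected components are the clusters; larger inflation gives finer
clusters.  The MCL implementation here is from scratch — the clustering
operator is the point of the module — while graph bookkeeping uses networkx.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, check_metadata

logger = logging.getLogger(__name__)

MODE_SAMPLE = "sample_sample"
MODE_PROBE = "probe_probe"


@dataclass(frozen=True)
class MCLConfig:
    """Markov Clustering settings; ``inflation`` is the usual MCLi knob."""

    inflation: float = 2.2
    expansion: int = 2
    prune_below: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 200
    self_loop_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError(f"inflation must be > 1, got {self.inflation}")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_below < 0 or self.self_loop_weight < 0:
            raise ValueError("prune_below and self_loop_weight must be >= 0")


@dataclass
class ClusterAssignment:
    """Node → 1-based cluster id, ids ordered by descending cluster size
    (ties broken by smallest member label)."""

    labels: pd.Series  # node -> cluster id
    n_clusters: int
    converged: bool = True

    @property
    def singletons(self) -> list:
        counts = self.labels.value_counts()
        single = set(counts.index[counts == 1])
        return list(self.labels.index[self.labels.isin(single)])

    def members(self, cluster_id: int) -> list:
        return list(self.labels.index[self.labels == cluster_id])


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def correlation_graph(
    matrix: ExpressionMatrix | pd.DataFrame,
    mode: str,
    threshold: float,
) -> nx.Graph:
    """Thresholded Pearson correlation graph.

    Edges exist where r strictly exceeds ``threshold`` (negative correlations
    never create edges against a positive threshold); zero-variance node
    vectors are dropped with a warning.  The graph carries ``mode`` and
    ``threshold`` attributes and edge weights = r.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if mode == MODE_SAMPLE:
        data = values.T  # rows = samples (nodes), observations = probes
    elif mode == MODE_PROBE:
        data = values  # rows = probes (nodes), observations = samples
    else:
        raise ValueError(f"mode must be {MODE_SAMPLE!r} or {MODE_PROBE!r}, got {mode!r}")
    if data.shape[1] < 3:
        raise ValueError("correlation_graph needs >= 3 observations per node")
    arr = data.to_numpy(float)
    sd = arr.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all node vectors have zero variance")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance nodes before correlation")
    nodes = list(data.index[keep])
    r = np.corrcoef(arr[keep])
    graph = nx.Graph(mode=mode, threshold=float(threshold))
    graph.add_nodes_from(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    hits = r[iu, ju] > threshold
    graph.add_weighted_edges_from(
        (nodes[i], nodes[j], float(r[i, j]))
        for i, j in zip(iu[hits], ju[hits])
    )
    return graph


# ---------------------------------------------------------------------------
# Markov Clustering
# ---------------------------------------------------------------------------

def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(graph: nx.Graph, cfg: MCLConfig | None = None) -> ClusterAssignment:
    """Cluster a weighted graph with Markov Clustering.

    Builds the weighted adjacency with ``self_loop_weight`` on the diagonal,
    column-normalizes, then iterates expansion/inflation/pruning to a fixed
    point.  Clusters are the connected components of the limit matrix's
    non-zero structure (the attractor systems together with the nodes they
    attract); a node reachable from several attractor systems lands in
    whichever component search reaches it, which the symmetrized-structure
    components make deterministic.
    """
    cfg = cfg or MCLConfig()
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("mcl_cluster: empty graph")
    n = len(nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    adj = adj + cfg.self_loop_weight * np.eye(n)
    m = _normalize_columns(adj)

    converged = False
    for _ in range(cfg.max_iter):
        expanded = np.linalg.matrix_power(m, cfg.expansion)
        inflated = _normalize_columns(expanded**cfg.inflation)
        inflated[inflated < cfg.prune_below] = 0.0
        inflated = _normalize_columns(inflated)
        # stochastic-matrix invariant is load-bearing for the attractor
        # interpretation; a violation means numerical trouble, so fail loudly
        if np.abs(inflated.sum(axis=0) - 1.0).max() > 1e-9:
            raise FloatingPointError("MCL column sums drifted from 1")
        delta = np.abs(inflated - m).max()
        m = inflated
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", cfg.max_iter)

    structure = (m > 0) | (m.T > 0)
    comp_graph = nx.from_numpy_array(structure.astype(float))
    components = [sorted(c) for c in nx.connected_components(comp_graph)]
    # order clusters by descending size, ties by smallest member label
    components.sort(key=lambda c: (-len(c), str(nodes[min(c)])))
    label_of = {}
    for cid, comp in enumerate(components, start=1):
        for idx in comp:
            label_of[nodes[idx]] = cid
    labels = pd.Series([label_of[n] for n in nodes], index=pd.Index(nodes), dtype=int)
    return ClusterAssignment(labels=labels, n_clusters=len(components), converged=converged)


# ---------------------------------------------------------------------------
# exact Fisher / chi-squared cluster-trait association
# ---------------------------------------------------------------------------

def _fisher_exact_integer(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for an r×2 table by exhaustive enumeration
    with exact integer weights.

    Each candidate table with the observed margins has probability
    proportional to prod_i C(row_i, a_i); comparing and summing these integer
    weights makes tie handling exact, and the final division by C(N, c1)
    happens once in floating point.
    """
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    obs_weight = math.prod(math.comb(int(rows[i]), int(table[i, 0])) for i in range(len(rows)))

    total = 0
    extreme = 0

    def recurse(i: int, remaining: int, weight: int) -> None:
        nonlocal total, extreme
        if i == len(rows) - 1:
            if remaining <= rows[i]:
                w = weight * math.comb(int(rows[i]), remaining)
                total += w
                if w <= obs_weight:
                    extreme += w
            return
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, weight * math.comb(int(rows[i]), a))

    recurse(0, c1, 1)
    return min(1.0, extreme / total)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table (sum of hypergeometric
    probabilities of tables at most as probable as the observed one),
    computed with exact integer arithmetic."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    return _fisher_exact_integer(table)


def cluster_trait_association(
    assignment: ClusterAssignment,
    metadata: pd.DataFrame,
    trait: str | pd.Series,
) -> dict:
    """Association between cluster membership and a binary trait.

    Builds the cluster × trait contingency table, uses Fisher's exact test
    when any expected cell count is < 5 (exact enumeration while the table
    is small, chi-squared fallback with a warning otherwise) and Pearson's
    chi-squared otherwise.  Returns test name, statistic, p-value and table.
    """
    if isinstance(trait, str):
        md = check_metadata(metadata)
        trait_values = md.loc[assignment.labels.index, trait]
    else:
        trait_values = trait.loc[assignment.labels.index]
    levels = sorted(pd.unique(trait_values.astype(str)))
    if len(levels) != 2:
        raise ValueError(f"trait must be binary, found levels {levels}")
    table = pd.crosstab(assignment.labels, trait_values.astype(str))
    table = table.reindex(columns=levels, fill_value=0)
    arr = table.to_numpy(int)

    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        warnings.warn("degenerate contingency table (zero margin); p-value = 1")
        return {"test": "degenerate", "statistic": float("nan"), "pvalue": 1.0, "table": table}

    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected < 5).any():
        if arr.shape[0] == 2:
            p = fisher_exact_2x2(arr)
            return {"test": "fisher_exact", "statistic": float("nan"), "pvalue": p, "table": table}
        if arr.sum() <= 60 and arr.shape[0] <= 8:
            p = _fisher_exact_integer(arr)
            return {"test": "fisher_exact", "statistic": float("nan"), "pvalue": p, "table": table}
        warnings.warn("table too large for exact enumeration; chi-squared fallback")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return {"test": "chi_squared", "statistic": float(stat), "pvalue": float(p), "table": table}


# ---------------------------------------------------------------------------
# cluster expression profiles
# ---------------------------------------------------------------------------

def cluster_profiles(
    matrix: ExpressionMatrix | pd.DataFrame,
    assignment: ClusterAssignment,
) -> dict[int, pd.DataFrame]:
    """Per-cluster mean expression profile across samples with standard
    errors (SD/√cluster size; singletons get SE 0)."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    profiles: dict[int, pd.DataFrame] = {}
    for cid in range(1, assignment.n_clusters + 1):
        members = assignment.members(cid)
        sub = values.loc[members]
        mean = sub.mean(axis=0)
        if len(members) == 1:
            se = pd.Series(0.0, index=mean.index)
        else:
            se = sub.std(axis=0, ddof=1) / np.sqrt(len(members))
        profiles[cid] = pd.DataFrame({"mean": mean, "se": se})
    return profiles


def export_graphml(
    graph: nx.Graph,
    path,
    node_attributes: pd.DataFrame | None = None,
    assignment: ClusterAssignment | None = None,
) -> None:
    """Write a graph as GraphML with optional per-node metadata columns and
    cluster labels attached as node attributes."""
    g = graph.copy()
    if node_attributes is not None:
        for col in node_attributes.columns:
            nx.set_node_attributes(
                g,
                {n: node_attributes.loc[n, col] for n in g.nodes if n in node_attributes.index},
                name=str(col),
            )
    if assignment is not None:
        nx.set_node_attributes(
            g, {n: int(assignment.labels[n]) for n in g.nodes}, name="cluster"
        )
    nx.write_graphml(g, path)
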