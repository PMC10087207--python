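"""Correlation networks, Markov clustering and over-representation analysis.

Gene-gene co-expression graphs connect genes whose expression profiles
correlate above a Pearson threshold, keeping only sufficiently large
connected components; sample-sample graphs optionally restrict edges to
k-nearest-neighbour lists.  Markov clustering (MCL) partitions a graph by
alternately squaring (expansion) and elementwise powering (inflation) a
column-stochastic flow matrix until it stabilizes.  Gene-set enrichment of
a query against a universe uses the hypergeometric upper tail with
minimum-overlap and fold-enrichment gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .diffexpr import bh_adjust
from .io import ExpressionMatrix

__all__ = [
    "CorrelationGraph",
    "Clustering",
    "gene_gene_graph",
    "mcl_cluster",
    "sample_graph",
    "kmeans_cluster",
    "hypergeom_ora",
]


@dataclass(frozen=True)
class CorrelationGraph:
    """Undirected graph with Pearson-r edge weights and its build record."""

    graph: nx.Graph
    record: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("correlation graph must not contain self-edges")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "r"])


@dataclass(frozen=True)
class Clustering:
    """Node-to-cluster assignment; ids contiguous from 1, by descending size."""

    assignments: pd.Series
    method: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(self.assignments.unique())
        if len(self.assignments) and ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous starting at 1")
        sizes = self.assignments.value_counts().reindex(ids)
        if (sizes.diff().dropna() > 0).any():
            raise ValueError("cluster ids must be ordered by descending size")

    def members(self, cid: int) -> list:
        return sorted(self.assignments.index[self.assignments == cid])

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) if len(self.assignments) else 0


def _relabel_by_size(groups: Iterable[Iterable]) -> pd.Series:
    ordered = sorted((sorted(g) for g in groups), key=lambda g: (-len(g), g))
    out: dict = {}
    for cid, members in enumerate(ordered, start=1):
        for m in members:
            out[m] = cid
    return pd.Series(out)


def gene_gene_graph(
    fpkm: ExpressionMatrix,
    r_min: float = 0.84,
    min_fpkm: float = 1.0,
    min_component: int = 10,
) -> CorrelationGraph:
    """Gene co-expression graph at Pearson r >= ``r_min``.

    Genes must reach ``min_fpkm`` in at least one sample to enter; genes
    with zero variance are excluded with a warning (their correlation is
    undefined).  Connected components smaller than ``min_component`` are
    dropped entirely.
    """
    if fpkm.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for gene-gene correlation")
    expressed = fpkm.values.index[(fpkm.values >= min_fpkm).any(axis=1)]
    sub = fpkm.values.loc[expressed]
    var = sub.var(axis=1, ddof=0)
    flat = list(sub.index[var == 0])
    if flat:
        warnings.warn(f"excluding {len(flat)} zero-variance gene(s) from the network")
        sub = sub.loc[var > 0]
    genes = list(sub.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        r = np.corrcoef(sub.to_numpy())
        iu, ju = np.triu_indices(len(genes), k=1)
        keep = r[iu, ju] >= r_min
        g.add_weighted_edges_from(
            (genes[i], genes[j], float(r[i, j])) for i, j in zip(iu[keep], ju[keep])
        )
    for comp in list(nx.connected_components(g)):
        if len(comp) < min_component:
            g.remove_nodes_from(comp)
    return CorrelationGraph(
        g,
        {
            "kind": "gene",
            "r_min": r_min,
            "min_fpkm": min_fpkm,
            "min_component": min_component,
            "n_zero_variance_excluded": len(flat),
        },
    )


def _mcl_iterate(
    M: np.ndarray, inflation: float, prune: float, tol: float, max_iter: int
) -> tuple[np.ndarray, bool]:
    for _ in range(max_iter):
        new = M @ M                      # expansion
        new = new**inflation             # inflation
        colsum = new.sum(axis=0)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if prune > 0:
            new[new < prune] = 0.0
            colsum = new.sum(axis=0)
            colsum[colsum == 0] = 1.0
            new /= colsum
        if np.abs(new - M).max() < tol:
            return new, True
        M = new
    return M, False


def mcl_cluster(
    graph: CorrelationGraph,
    inflation: float = 1.8,
    prune: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> Clustering:
    """Markov clustering of a weighted graph.

    Each node receives a self-loop weighted by its maximum incident edge
    weight (1 for isolated nodes); the matrix is column-normalized and
    iterated with expansion (matrix square) then inflation (elementwise
    power ``inflation``, renormalize), pruning entries below ``prune``.
    Clusters are connected components of the converged flow's support.
    Non-convergence within ``max_iter`` returns the current interpretation
    flagged in ``params['converged']``.
    """
    nodes = sorted(graph.graph.nodes)
    if not nodes:
        raise ValueError("cannot cluster an empty graph")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, d in graph.graph.edges(data=True):
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = d.get("weight", 1.0)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M /= M.sum(axis=0)
    M, converged = _mcl_iterate(M, inflation, prune, tol, max_iter)
    support = nx.Graph()
    support.add_nodes_from(range(n))
    ii, jj = np.nonzero(M > max(tol, 1e-9))
    support.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [[nodes[i] for i in comp] for comp in nx.connected_components(support)]
    assignments = _relabel_by_size(comps)
    return Clustering(
        assignments,
        "MCL",
        {"inflation": inflation, "prune": prune, "tol": tol, "converged": converged},
    )


def sample_graph(
    expr: ExpressionMatrix,
    gene_subset: Iterable[str],
    r_min: float,
    knn: int | None = None,
    mutual: bool = False,
) -> CorrelationGraph:
    """Sample-sample correlation graph over a gene subset.

    Edges require Pearson r strictly above ``r_min``; with ``knn`` set, an
    edge additionally requires that at least one endpoint ranks the other
    within its ``knn`` strongest correlations (both endpoints, if
    ``mutual``).
    """
    genes = [g for g in gene_subset if g in expr.values.index]
    if not genes:
        raise ValueError("gene subset is empty or disjoint from the matrix")
    if expr.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sub = expr.values.loc[genes].to_numpy(dtype=float)
    samples = list(expr.samples)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(sub.T)
    r = np.nan_to_num(r, nan=-np.inf)
    np.fill_diagonal(r, -np.inf)
    nominates = None
    if knn is not None:
        order = np.argsort(-r, axis=1, kind="stable")
        nominates = np.zeros_like(r, dtype=bool)
        for i in range(len(samples)):
            nominates[i, order[i, :knn]] = True
    g = nx.Graph()
    g.add_nodes_from(samples)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if not r[i, j] > r_min:
                continue
            if nominates is not None:
                ok = (nominates[i, j] and nominates[j, i]) if mutual else (nominates[i, j] or nominates[j, i])
                if not ok:
                    continue
            g.add_edge(samples[i], samples[j], weight=float(r[i, j]))
    return CorrelationGraph(
        g, {"kind": "sample", "r_min": r_min, "knn": knn, "mutual": mutual, "n_genes": len(genes)}
    )


def kmeans_cluster(matrix: pd.DataFrame, k: int, seed: int, n_init: int = 25) -> Clustering:
    """K-means (k-means++ initialization, ``n_init`` restarts) on the rows.

    Deterministic for a fixed seed; requires at least ``k`` distinct rows.
    """
    distinct = np.unique(matrix.to_numpy(dtype=float), axis=0)
    if distinct.shape[0] < k:
        raise ValueError(f"need >= {k} distinct rows, got {distinct.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    groups = [list(matrix.index[labels == c]) for c in range(k)]
    assignments = _relabel_by_size([g for g in groups if g])
    assignments = assignments.loc[matrix.index]
    return Clustering(assignments, "kmeans", {"k": k, "seed": seed, "n_init": n_init})


def hypergeom_ora(
    query: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    min_overlap: int = 3,
    p_cut: float = 0.01,
    min_enrichment: float = 1.5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in annotated sets.

    Each set is first intersected with the universe; the upper-tail
    probability of observing at least the attained overlap is computed from
    the hypergeometric distribution, BH-adjusted across all tested sets,
    and the report keeps sets with overlap >= ``min_overlap``,
    p < ``p_cut`` and fold enrichment >= ``min_enrichment``.
    """
    q, u = set(query), set(universe)
    if not q <= u:
        raise ValueError(f"query contains genes outside the universe: {sorted(q - u)[:5]}")
    N, n = len(u), len(q)
    rows = []
    for name in sets:
        S = set(sets[name]) & u
        K = len(S)
        if K == 0:
            continue
        k = len(q & S)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append((name, k, K, n, N, p, fold))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "pvalue", "fold_enrichment"]
    ).set_index("set")
    if len(df):
        df["adj_pvalue"] = bh_adjust(df["pvalue"])
        keep = (
            (df["overlap"] >= min_overlap)
            & (df["pvalue"] < p_cut)
            & (df["fold_enrichment"] >= min_enrichment)
        )
        df = df.loc[keep].sort_values("pvalue")
    else:
        df["adj_pvalue"] = pd.Series(dtype=float)
    return df
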