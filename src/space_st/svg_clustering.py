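"""Step 2: group SVGs by spatial pattern via covariate-adjusted re-testing.

For each detected SVG ``j`` a related set ``S_j`` of co-expressed SVGs is
selected by a marginal correlation test. The spatial test is then re-run with
the related genes (or, when ``|S_j| > 3``, the principal components explaining
at least 80% of their variance) as covariates: if the shared signal explains
the spatial pattern the adjusted test loses significance, marking dependency;
genes that stay significant after adjustment carry a unique pattern and
become singletons. Non-unique SVGs contribute edges to their related genes,
weighted by |Pearson r|; Leiden community detection on the resulting weighted
graph yields the spatial-pattern gene clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix
from .svg_test import KernelEigen, combine_cauchy, combine_minp, fit_null
from .chi2mix import mixture_pvalue_fast

logger = logging.getLogger(__name__)


@dataclass
class RelatedSet:
    target: str
    members: list[str]
    correlations: dict[str, float] = field(default_factory=dict)
    adjusted_p: dict[str, float] = field(default_factory=dict)


@dataclass
class AdjustedResult:
    gene_id: str
    k_j: int  # PCs used; 0 when raw member vectors (|S_j| <= 3) or none
    p_combined: float
    unique_pattern: bool = False


@dataclass
class DependencyGraph:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # undirected, weight in (0, 1]

    def to_igraph(self) -> ig.Graph:
        index = {g: i for i, g in enumerate(self.nodes)}
        g = ig.Graph(n=len(self.nodes))
        g.vs["name"] = list(self.nodes)
        if self.edges:
            g.add_edges([(index[a], index[b]) for a, b, _ in self.edges])
            g.es["weight"] = [w for _, _, w in self.edges]
        return g


def _pearson_all(target: np.ndarray, others: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided test p of target against each row of others."""
    n = target.size
    tc = target - target.mean()
    oc = others - others.mean(axis=1, keepdims=True)
    denom = np.sqrt((tc @ tc) * np.einsum("ij,ij->i", oc, oc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (oc @ tc) / denom
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def select_related(
    expr_svgs: ExpressionMatrix,
    target: str,
    alpha: float = 0.05,
    method: str = "cor_test",
    abs_r_threshold: float = 0.3,
) -> RelatedSet:
    """Select the SVGs correlated with ``target``.

    ``cor_test`` (default): Pearson correlation test, BH-adjusted across the
    candidate genes for this target, members at adjusted p <= alpha.
    Alternatives: ``spearman`` (same rule on rank correlations) and ``abs_r``
    (plain |r| >= threshold).
    """
    if target not in expr_svgs.gene_ids:
        raise ValueError(f"target {target!r} is not among the SVGs")
    idx = expr_svgs.gene_ids.index(target)
    y = expr_svgs.values[idx]
    if np.var(y) == 0:
        raise ValueError("zero-variance target gene")
    others = np.delete(expr_svgs.values, idx, axis=0)
    other_ids = [g for g in expr_svgs.gene_ids if g != target]
    if not other_ids:
        return RelatedSet(target, [])
    if method == "spearman":
        ranks = stats.rankdata(others, axis=1)
        r, p = _pearson_all(stats.rankdata(y), ranks)
    else:
        r, p = _pearson_all(y, others)
    if method == "abs_r":
        keep = np.abs(r) >= abs_r_threshold
        padj = p
    else:
        _, padj, _, _ = multipletests(p, method="fdr_bh")
        keep = padj <= alpha
    members = [g for g, k in zip(other_ids, keep) if k]
    return RelatedSet(
        target,
        members,
        {g: float(rv) for g, rv, k in zip(other_ids, r, keep) if k},
        {g: float(pv) for g, pv, k in zip(other_ids, padj, keep) if k},
    )


def pc_covariates(member_values: np.ndarray, var_threshold: float = 0.8) -> tuple[np.ndarray, int]:
    """Covariates from a related set (genes x spots).

    With three or fewer members the raw member expression vectors are used
    (k_j reported as 0); otherwise the top principal-component scores of the
    centered member matrix, with k_j the smallest count explaining at least
    ``var_threshold`` of the total variance.
    """
    member_values = np.atleast_2d(np.asarray(member_values, dtype=float))
    g = member_values.shape[0]
    if g == 0:
        raise ValueError("empty related set")
    if g <= 3:
        return member_values.T.copy(), 0
    Xs = member_values.T - member_values.T.mean(axis=0)  # spots x genes
    if not np.any(Xs):
        raise ValueError("related set has zero total variance")
    # eigendecompose on the smaller side; large related sets make a full SVD
    # needlessly expensive
    n, g = Xs.shape
    if g <= n:
        ev, V = np.linalg.eigh(Xs.T @ Xs)
        ev, V = ev[::-1], V[:, ::-1]
        frac = np.cumsum(ev) / np.sum(ev)
        k_j = int(np.searchsorted(frac, var_threshold) + 1)
        scores = Xs @ V[:, :k_j]
    else:
        ev, U = np.linalg.eigh(Xs @ Xs.T)
        ev, U = ev[::-1], U[:, ::-1]
        frac = np.cumsum(ev) / np.sum(ev)
        k_j = int(np.searchsorted(frac, var_threshold) + 1)
        scores = U[:, :k_j] * np.sqrt(np.clip(ev[:k_j], 0, None))
    return scores, k_j


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Drop columns until X is full column rank (QR with column pivoting)."""
    from scipy.linalg import qr

    R, piv = qr(X, mode="r", pivoting=True)[0:2]
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return X
    logger.warning("covariates collinear with the design; dropping redundant columns")
    return X[:, np.sort(piv[:rank])]


def adjusted_test(
    y: np.ndarray,
    covariates: np.ndarray | None,
    eigens: list[KernelEigen],
    combine: str = "cauchy",
) -> tuple[float, int]:
    """Re-run the spatial score test with the related-gene covariates.

    Returns (combined adjusted p, rank of the covariate design incl.
    intercept).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        X = _drop_collinear(np.column_stack([X, covariates]))
    fit = fit_null(y, X)
    if fit.degenerate:
        return 1.0, X.shape[1]
    ps = []
    for ke in eigens:
        lam = fit.sigma2 * ke.projected_eigs(X)
        T = ke.statistic(fit.residuals)
        p, _ = mixture_pvalue_fast(lam, T)
        ps.append(p)
    combiner = {"cauchy": combine_cauchy, "minp": combine_minp}[combine]
    return combiner(ps), X.shape[1]


def build_graph(
    svg_ids: list[str],
    related: dict[str, RelatedSet],
    adjusted: dict[str, AdjustedResult],
) -> DependencyGraph:
    """Weighted dependency graph: nodes are SVGs; every non-unique SVG j is
    connected to each member of S_j with weight |Pearson r|; parallel edges
    keep the maximum weight; unique-pattern SVGs contribute no edges."""
    weights: dict[tuple[str, str], float] = {}
    for gid in svg_ids:
        res = adjusted[gid]
        if res.unique_pattern:
            continue
        rel = related[gid]
        for member in rel.members:
            if member == gid or member not in adjusted:
                continue
            key = tuple(sorted((gid, member)))
            w = abs(rel.correlations.get(member, 1.0))
            if w > 0:
                weights[key] = max(weights.get(key, 0.0), w)
    edges = [(a, b, w) for (a, b), w in sorted(weights.items())]
    return DependencyGraph(list(svg_ids), edges)


def cluster_genes(
    graph: DependencyGraph,
    resolution: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Leiden modularity clustering of the dependency graph.

    Isolated nodes become singletons; clusters smaller than ``min_size`` are
    flagged singleton-like but keep their labels. Returns a DataFrame with
    columns gene_id, cluster, singleton.
    """
    if not graph.nodes:
        raise ValueError("empty dependency graph")
    g = graph.to_igraph()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if graph.edges else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    sizes = np.bincount(labels)
    singleton = sizes[labels] < min_size
    return pd.DataFrame(
        {"gene_id": graph.nodes, "cluster": labels, "singleton": singleton}
    )


def classify_svgs(
    expr: ExpressionMatrix,
    svg_table: pd.DataFrame,
    eigens: list[KernelEigen],
    alpha: float = 0.05,
    selection: str = "cor_test",
    var_threshold: float = 0.8,
    fdr: float = 0.05,
    resolution: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    combine: str = "cauchy",
) -> tuple[pd.DataFrame, DependencyGraph]:
    """Full step 2 over all detected SVGs.

    Returns (clusters DataFrame with columns gene_id, cluster, singleton,
    unique_pattern, k_j, adjusted_p; the dependency graph).
    """
    svg_ids = svg_table.loc[svg_table["is_svg"], "gene_id"].tolist()
    if not svg_ids:
        raise ValueError("no SVGs detected in step 1")
    # per-gene covariate designs force a fresh projected spectrum per SVG and
    # kernel; a slightly tighter tail truncation keeps that affordable at an
    # error far below the p-value tolerance
    eigens = [ke.trim(1e-5) for ke in eigens]
    expr_svgs = expr.subset_genes(svg_ids)
    values = {g: expr_svgs.values[i] for i, g in enumerate(svg_ids)}

    related: dict[str, RelatedSet] = {}
    adjusted: dict[str, AdjustedResult] = {}
    for gid in svg_ids:
        rel = select_related(expr_svgs, gid, alpha=alpha, method=selection)
        related[gid] = rel
        if rel.members:
            member_vals = np.vstack([values[g] for g in rel.members])
            covs, k_j = pc_covariates(member_vals, var_threshold)
        else:
            covs, k_j = None, 0
        p_adj, _ = adjusted_test(values[gid], covs, eigens, combine=combine)
        adjusted[gid] = AdjustedResult(gid, k_j, p_adj)

    p_adj_all = np.array([adjusted[g].p_combined for g in svg_ids])
    _, q_adj, _, _ = multipletests(p_adj_all, method="fdr_bh")
    for gid, q in zip(svg_ids, q_adj):
        adjusted[gid].unique_pattern = bool(q <= fdr)

    graph = build_graph(svg_ids, related, adjusted)
    clusters = cluster_genes(graph, resolution=resolution, seed=seed, min_size=min_size)
    clusters["unique_pattern"] = [adjusted[g].unique_pattern for g in clusters["gene_id"]]
    clusters["k_j"] = [adjusted[g].k_j for g in clusters["gene_id"]]
    clusters["adjusted_p"] = [adjusted[g].p_combined for g in clusters["gene_id"]]
    return clusters, graph
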