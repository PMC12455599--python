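"""Model/Results facade orchestrating the full framework.

``SpaceModel`` holds the data (normalized expression, coordinates, optional
covariates) and configuration; ``fit()`` runs SVG detection, spatial-pattern
clustering of the SVGs and (optionally) domain detection, returning a
``SpaceResults`` with the per-stage tables, an evaluation helper and a
``summary()`` report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as io_mod
from .config import SpaceConfig
from .datatypes import ExpressionMatrix, RawCounts, SpatialCoords
from .domains import (
    AggregatedEmbedding,
    ClusterEmbedding,
    aggregate,
    baseline_pipeline,
    cluster_spots,
    embed_cluster,
)
from .kernels import make_kernel_bank
from .metrics import ari, pas
from .svg_clustering import DependencyGraph, classify_svgs
from .svg_test import KernelEigen, detect_svgs

logger = logging.getLogger(__name__)


class SpaceModel:
    """Spatially-variable-gene clustering and domain-detection model.

    Parameters
    ----------
    expr : ExpressionMatrix
        Normalized expression, genes x spots.
    coords : SpatialCoords
        Spot coordinates aligned with ``expr``.
    covariates : ndarray, optional
        Extra spot-level covariates for the step-1 null model (an intercept
        is always included).
    config : SpaceConfig, optional
        Stage parameters; defaults follow the framework's standard settings.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        coords: SpatialCoords,
        covariates: np.ndarray | None = None,
        config: SpaceConfig | None = None,
    ):
        self.config = config or SpaceConfig()
        expr, coords = io_mod.align_spots(expr, coords)
        self.expr = expr
        self.coords = coords
        n = expr.n_spots
        X = np.ones((n, 1))
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                raise ValueError("covariate rows must match the number of spots")
            X = np.column_stack([X, covariates])
        self.X = X

    @classmethod
    def from_dataframes(
        cls,
        expr_df: pd.DataFrame,
        coords_df: pd.DataFrame,
        normalized: bool = True,
        **kwargs,
    ) -> "SpaceModel":
        """Build from a genes-x-spots DataFrame and a (spot_id, x, y) table."""
        expr = ExpressionMatrix(
            expr_df.to_numpy(dtype=float),
            [str(g) for g in expr_df.index],
            [str(s) for s in expr_df.columns],
            normalized,
        )
        coords = SpatialCoords(
            coords_df.iloc[:, 1:3].to_numpy(dtype=float),
            coords_df.iloc[:, 0].astype(str).tolist(),
        )
        return cls(expr, coords, **kwargs)

    @classmethod
    def from_counts(
        cls,
        counts: RawCounts,
        coords: SpatialCoords,
        min_frac: float | None = None,
        normalize: str | None = None,
        config: SpaceConfig | None = None,
        **kwargs,
    ) -> "SpaceModel":
        """Build from raw counts: sparse-gene filter then normalization."""
        config = config or SpaceConfig()
        pp = config.preprocess
        counts = io_mod.filter_genes(counts, min_frac if min_frac is not None else pp.min_frac)
        expr = io_mod.normalize(counts, normalize if normalize is not None else pp.normalize)
        return cls(expr, coords, config=config, **kwargs)

    def fit(self, detect_domains: bool = True, baseline: bool = False) -> "SpaceResults":
        """Run the pipeline; returns a :class:`SpaceResults`."""
        cfg = self.config
        timings: dict[str, float] = {}
        t0 = time.time()
        bank = make_kernel_bank(
            self.coords,
            n_each=cfg.kernel.n_each,
            quantiles=cfg.kernel.quantiles,
            families=tuple(cfg.kernel.families),
        )
        eigens = [KernelEigen.from_kernel(k) for k in bank]
        timings["kernels"] = time.time() - t0

        t0 = time.time()
        svg_table = detect_svgs(
            self.expr,
            self.coords,
            X=self.X,
            fdr=cfg.test.fdr,
            bank=eigens,
            combine=cfg.test.combine,
        )
        timings["svg_test"] = time.time() - t0

        t0 = time.time()
        gene_clusters, graph = classify_svgs(
            self.expr,
            svg_table,
            eigens,
            alpha=cfg.step2.alpha,
            selection=cfg.step2.selection,
            var_threshold=cfg.step2.var_threshold,
            fdr=cfg.test.fdr,
            resolution=cfg.step2.resolution,
            seed=cfg.step2.seed,
            min_size=cfg.step2.min_size,
            combine=cfg.test.combine,
        )
        timings["svg_clustering"] = time.time() - t0

        results = SpaceResults(
            model=self,
            svg_table=svg_table,
            gene_clusters=gene_clusters,
            graph=graph,
            timings=timings,
        )
        if detect_domains:
            t0 = time.time()
            results.embeddings = self._embed_clusters(gene_clusters)
            results.embedding = aggregate(results.embeddings)
            results.domain_labels = cluster_spots(
                results.embedding,
                self.coords,
                mode=cfg.domains.mode,
                k_d=cfg.domains.k_d,
                resolution=cfg.domains.resolution,
                method=cfg.domains.method,
                seed=cfg.domains.seed,
                n_neighbors=cfg.domains.n_neighbors,
            )
            timings["domains"] = time.time() - t0
        if baseline:
            t0 = time.time()
            results.baseline_labels = baseline_pipeline(
                self.expr,
                self.coords,
                svg_table,
                n_top_svgs=cfg.baseline.n_top_svgs,
                n_pcs=cfg.baseline.n_pcs,
                embed_method=cfg.embed.method if cfg.embed.method != "external" else "smoothed_pca",
                bandwidth_quantile=cfg.embed.bandwidth_quantile,
                mode=cfg.domains.mode,
                k_d=cfg.domains.k_d,
                resolution=cfg.domains.resolution,
                method=cfg.domains.method,
                seed=cfg.domains.seed,
                n_neighbors=cfg.domains.n_neighbors,
            )
            timings["baseline"] = time.time() - t0
        return results

    def _embed_clusters(self, gene_clusters: pd.DataFrame) -> list[ClusterEmbedding]:
        cfg = self.config
        use = gene_clusters if cfg.embed.include_singletons else gene_clusters[~gene_clusters["singleton"]]
        if use.empty:
            logger.warning("no main clusters (all singletons); embedding every cluster")
            use = gene_clusters
        embeddings = []
        for cl, grp in use.groupby("cluster"):
            method = cfg.embed.method
            external = cfg.embed.external_paths.get(cl) if method == "external" else None
            if method == "external" and external is None:
                method = "smoothed_pca"
            embeddings.append(
                embed_cluster(
                    self.expr.subset_genes(grp["gene_id"].tolist()),
                    self.coords,
                    cluster=int(cl),
                    n_pcs=cfg.embed.n_pcs,
                    method=method,
                    bandwidth_quantile=cfg.embed.bandwidth_quantile,
                    external_path=external,
                )
            )
        return embeddings


@dataclass
class SpaceResults:
    """Fitted results: SVG calls, gene clusters, domains, diagnostics."""

    model: SpaceModel
    svg_table: pd.DataFrame
    gene_clusters: pd.DataFrame
    graph: DependencyGraph
    timings: dict[str, float] = field(default_factory=dict)
    embeddings: list[ClusterEmbedding] = field(default_factory=list)
    embedding: AggregatedEmbedding | None = None
    domain_labels: np.ndarray | None = None
    baseline_labels: np.ndarray | None = None

    @property
    def n_svgs(self) -> int:
        return int(self.svg_table["is_svg"].sum())

    @property
    def main_clusters(self) -> pd.Series:
        """Sizes of the non-singleton gene clusters."""
        main = self.gene_clusters[~self.gene_clusters["singleton"]]
        return main.groupby("cluster").size().sort_values(ascending=False)

    def evaluate(
        self, truth_domains=None, truth_gene_clusters=None
    ) -> dict[str, float]:
        """ARI/PAS against supplied ground truth."""
        out: dict[str, float] = {}
        if truth_domains is not None and self.domain_labels is not None:
            out["domain_ari"] = ari(self.domain_labels, truth_domains)
            out["domain_pas"] = pas(self.domain_labels, self.model.coords)
            if self.baseline_labels is not None:
                out["baseline_ari"] = ari(self.baseline_labels, truth_domains)
                out["baseline_pas"] = pas(self.baseline_labels, self.model.coords)
        if truth_gene_clusters is not None:
            truth = pd.Series(truth_gene_clusters)
            pred = self.gene_clusters.set_index("gene_id")["cluster"]
            common = pred.index.intersection(truth.index)
            out["gene_cluster_ari"] = ari(pred.loc[common], truth.loc[common])
        return out

    def summary(self) -> str:
        lines = [
            "SPACE framework results",
            "=======================",
            f"genes tested        : {len(self.svg_table)}",
            f"spots               : {self.model.expr.n_spots}",
            f"SVGs detected (m1)  : {self.n_svgs}",
            f"unique-pattern SVGs : {int(self.gene_clusters['unique_pattern'].sum())}",
        ]
        sizes = self.main_clusters
        lines.append(f"main gene clusters  : {len(sizes)} " f"(sizes {', '.join(map(str, sizes.tolist()))})")
        if self.domain_labels is not None:
            lines.append(f"spatial domains     : {len(np.unique(self.domain_labels))}")
            lines.append(f"domain PAS          : {pas(self.domain_labels, self.model.coords):.6f}")
        for stage, secs in self.timings.items():
            lines.append(f"time [{stage:14s}]: {secs:.2f} s")
        return "\n".join(lines)
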