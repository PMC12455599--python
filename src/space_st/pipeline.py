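"""End-to-end runs with file inputs/outputs (the engine behind the CLI)."""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import io as io_mod
from .config import SpaceConfig
from .model import SpaceModel, SpaceResults
from .simulate import (
    DomainSimConfig,
    Scenario1Config,
    simulate_domain_dataset,
    simulate_scenario1,
    write_dataset,
)

logger = logging.getLogger(__name__)


def run_space(
    expr_path: str,
    coords_path: str,
    outdir: str,
    config: SpaceConfig | None = None,
    baseline: bool = False,
    truth_domains_path: str | None = None,
    expr_format: str | None = None,
    spots_as_rows: bool = False,
) -> SpaceResults:
    """Load data, run the framework, and write all tabular outputs.

    Outputs under ``outdir``: ``svg_table.tsv``, ``gene_clusters.tsv``,
    ``edges.tsv``, ``embedding.tsv``, ``domains.tsv`` (plus
    ``domains_baseline.tsv`` with ``baseline=True``) and ``summary.json``.
    """
    config = config or SpaceConfig()
    os.makedirs(outdir, exist_ok=True)
    coords = io_mod.load_coordinates(coords_path)
    if config.preprocess.normalize == "none":
        expr = io_mod.load_expression_matrix(expr_path, expr_format, spots_as_rows)
        model = SpaceModel(expr, coords, config=config)
    else:
        counts = io_mod.load_expression(expr_path, expr_format, spots_as_rows)
        model = SpaceModel.from_counts(counts, coords, config=config)
    results = model.fit(detect_domains=True, baseline=baseline)

    results.svg_table.to_csv(os.path.join(outdir, "svg_table.tsv"), sep="\t", index=False)
    results.gene_clusters.to_csv(os.path.join(outdir, "gene_clusters.tsv"), sep="\t", index=False)
    pd.DataFrame(results.graph.edges, columns=["gene_a", "gene_b", "weight"]).to_csv(
        os.path.join(outdir, "edges.tsv"), sep="\t", index=False
    )
    emb = pd.DataFrame(
        results.embedding.scores,
        index=pd.Index(model.expr.spot_ids, name="spot_id"),
        columns=[f"c{c}_pc{j + 1}" for c, j in results.embedding.provenance],
    )
    emb.to_csv(os.path.join(outdir, "embedding.tsv"), sep="\t")
    pd.DataFrame({"spot_id": model.expr.spot_ids, "label": results.domain_labels}).to_csv(
        os.path.join(outdir, "domains.tsv"), sep="\t", index=False
    )
    if results.baseline_labels is not None:
        pd.DataFrame(
            {"spot_id": model.expr.spot_ids, "label": results.baseline_labels}
        ).to_csv(os.path.join(outdir, "domains_baseline.tsv"), sep="\t", index=False)

    summary: dict = {
        "n_genes": model.expr.n_genes,
        "n_spots": model.expr.n_spots,
        "n_svgs": results.n_svgs,
        "main_cluster_sizes": results.main_clusters.tolist(),
        "n_domains": int(len(np.unique(results.domain_labels))),
        "timings": results.timings,
    }
    if truth_domains_path:
        truth = pd.read_csv(truth_domains_path, sep="\t")
        truth = truth.set_index(truth.columns[0]).iloc[:, 0].loc[model.expr.spot_ids]
        summary["metrics"] = results.evaluate(truth_domains=truth.to_numpy())
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("run complete: %d SVGs, %d domains", results.n_svgs, summary["n_domains"])
    return results


def run_simulate(which: str, outdir: str, config_path: str | None = None, **overrides) -> dict[str, str]:
    """Generate a simulated dataset on disk (``scenario1`` or ``domain``)."""
    params: dict = {}
    if config_path:
        import yaml

        with open(config_path) as fh:
            params = yaml.safe_load(fh) or {}
    params.update(overrides)
    if which == "scenario1":
        dataset = simulate_scenario1(Scenario1Config(**params))
    elif which == "domain":
        dataset = simulate_domain_dataset(DomainSimConfig(**params))
    else:
        raise ValueError(f"unknown simulation design: {which!r}")
    return write_dataset(dataset, outdir)
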