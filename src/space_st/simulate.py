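"""Ground-truth simulators for the two evaluation designs.

Scenario I (SVG classification): 53 genes x 2000 spots. Genes g1-g10 are
independent noise; g11-g20 are mutually correlated but non-spatial; g21-g30,
g31-g40 and g41-g50 carry spatial patterns 1-3 with a spatial-effect strength
increasing with gene index within each group and correlated within-group
noise (compound symmetry or AR(1)); g51-g53 each carry a unique pattern
(patterns 4-6) at a fixed strong effect.

Domain-template design (domain detection): a layered-tissue template with a
configurable number of curved, roughly equal-area bands (defaults: 3484
spots, 5 bands emulating four cortex layers plus white matter). 2000 of 4865
genes are made spatially variable, split 800/150/1050 across three clusters
overexpressed respectively in band 1, bands 2-4, and band 5; the rest are
noise genes. Gene baselines and noise scales are drawn from log-normal
distributions so the marginal mean/variance heterogeneity of spot-level data
is emulated.

All randomness flows from the config seed; identical configs give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, SpatialCoords

#: six distinguishable smooth fields on the unit square, all in [0, 1]
N_PATTERNS = 6


def pattern_value(pattern_id: int, s: np.ndarray) -> np.ndarray:
    """Evaluate spatial pattern ``pattern_id`` (1..6) at coordinates ``s``.

    ``s`` is (..., 2) in the unit square. The fields: 1 linear gradient,
    2 central radial hotspot, 3 off-center diagonal stripe, 4 two
    anti-diagonal hotspots, 5 periodic bands, 6 four corner hotspots; all
    valued in [0, 1] and constructed to be close to mutually uncorrelated
    over the tissue.
    """
    s = np.asarray(s, dtype=float)
    x, y = s[..., 0], s[..., 1]
    if pattern_id == 1:
        return x
    if pattern_id == 2:
        return np.exp(-((x - 0.5) ** 2 + (y - 0.5) ** 2) / (2 * 0.15**2))
    if pattern_id == 3:
        return np.exp(-((x - y - 0.3) ** 2) / (2 * 0.1**2))
    if pattern_id == 4:
        h1 = np.exp(-((x - 0.2) ** 2 + (y - 0.8) ** 2) / (2 * 0.12**2))
        h2 = np.exp(-((x - 0.8) ** 2 + (y - 0.2) ** 2) / (2 * 0.12**2))
        return np.maximum(h1, h2)
    if pattern_id == 5:
        return 0.5 * (1.0 + np.sin(2 * np.pi * 3 * y))
    if pattern_id == 6:
        corners = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
        fields = [
            np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.15**2)) for cx, cy in corners
        ]
        return np.maximum.reduce(fields)
    raise ValueError(f"unknown pattern id: {pattern_id}")


def _jittered_grid(n_spots: int, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
    """Roughly uniform spots on the unit square (jittered grid)."""
    side = int(np.ceil(np.sqrt(n_spots)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    pts = pts[rng.permutation(pts.shape[0])[:n_spots]]
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    pts -= pts.min(axis=0)
    pts /= pts.max(axis=0)
    return pts


def _group_correlation(size: int, rho: float, structure: str) -> np.ndarray:
    i = np.arange(size)
    if structure == "CS":
        C = np.full((size, size), rho)
        np.fill_diagonal(C, 1.0)
    elif structure == "AR1":
        C = rho ** np.abs(i[:, None] - i[None, :])
    else:
        raise ValueError(f"unknown correlation structure: {structure!r}")
    return C


def _correlated_noise(
    size: int, n: int, rho: float, structure: str, sd: float, rng: np.random.Generator
) -> np.ndarray:
    C = _group_correlation(size, rho, structure)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(size))
    return sd * (L @ rng.standard_normal((size, n)))


@dataclass
class Scenario1Config:
    n_spots: int = 2000
    n_noise: int = 10  # g1-g10, independent
    n_correlated: int = 10  # g11-g20, correlated non-spatial
    n_per_pattern: int = 10  # g21-g30 / g31-g40 / g41-g50, patterns 1-3
    n_unique: int = 3  # g51-g53, patterns 4-6
    rho: float = 0.6
    structure: str = "CS"  # or "AR1"
    effect_grid: tuple[float, ...] = tuple(np.linspace(0.2, 2.0, 10))
    unique_effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        grid = np.asarray(self.effect_grid, dtype=float)
        if len(grid) != self.n_per_pattern or np.any(np.diff(grid) <= 0):
            raise ValueError("effect_grid must be strictly increasing with one entry per gene")
        if self.structure not in ("CS", "AR1"):
            raise ValueError("structure must be CS or AR1")

    @property
    def n_genes(self) -> int:
        return self.n_noise + self.n_correlated + 3 * self.n_per_pattern + self.n_unique


@dataclass
class DomainTemplate:
    coords: SpatialCoords
    domains: np.ndarray  # integer band label per spot
    cluster_domains: dict[int, frozenset[int]]  # gene cluster -> overexpressed bands


@dataclass
class DomainSimConfig:
    n_spots: int = 3484
    n_domains: int = 5
    n_genes: int = 4865
    svg_counts: tuple[int, ...] = (800, 150, 1050)
    effect_size: float = 1.0  # overexpression shift, in units of a gene's noise sd
    mean_log_mu: float = 0.0  # log-normal gene baseline means
    mean_log_sd: float = 0.5
    sd_log_mu: float = -0.5  # log-normal gene noise scales
    sd_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.svg_counts):
            raise ValueError("all SVG cluster counts must be positive")
        if sum(self.svg_counts) > self.n_genes:
            raise ValueError("SVG counts exceed the total gene count")


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix
    coords: SpatialCoords
    gene_truth: "np.ndarray"  # label per gene
    domain_truth: np.ndarray | None = None  # label per spot (domain designs)


def simulate_scenario1(config: Scenario1Config | None = None) -> SimulatedDataset:
    """Simulate the SVG-classification design (defaults: 53 genes x 2000
    spots)."""
    cfg = config or Scenario1Config()
    rng = np.random.default_rng(cfg.seed)
    coords = _jittered_grid(cfg.n_spots, rng)
    n = cfg.n_spots

    blocks: list[np.ndarray] = []
    truth: list[str] = []
    # independent noise genes
    blocks.append(cfg.noise_sd * rng.standard_normal((cfg.n_noise, n)))
    truth += ["noise"] * cfg.n_noise
    # correlated non-spatial genes
    blocks.append(_correlated_noise(cfg.n_correlated, n, cfg.rho, cfg.structure, cfg.noise_sd, rng))
    truth += ["correlated"] * cfg.n_correlated
    # three patterned groups with increasing effect strength
    effects = np.asarray(cfg.effect_grid, dtype=float)
    for p in (1, 2, 3):
        mean = pattern_value(p, coords)[None, :] * effects[:, None]
        noise = _correlated_noise(cfg.n_per_pattern, n, cfg.rho, cfg.structure, cfg.noise_sd, rng)
        blocks.append(mean + noise)
        truth += [f"pattern{p}"] * cfg.n_per_pattern
    # unique-pattern genes
    for i in range(cfg.n_unique):
        p = 4 + i
        y = cfg.unique_effect * pattern_value(p, coords) + cfg.noise_sd * rng.standard_normal(n)
        blocks.append(y[None, :])
        truth.append(f"unique{p}")

    values = np.vstack(blocks)
    gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    spot_ids = [f"s{i + 1}" for i in range(n)]
    expr = ExpressionMatrix(values, gene_ids, spot_ids, normalized=True)
    return SimulatedDataset(expr, SpatialCoords(coords, spot_ids), np.array(truth))


def builtin_template(n_spots: int = 3484, n_domains: int = 5, seed: int = 0) -> DomainTemplate:
    """Layered-tissue template: curved, roughly equal-area parallel bands.

    Band 0 plays the role of the outermost layer and the last band the
    white-matter analog; gene cluster 1 maps to band 0, cluster 2 to the
    middle bands, cluster 3 to the last band.
    """
    if n_domains < 2:
        raise ValueError("need at least two domains")
    rng = np.random.default_rng(seed)
    coords = _jittered_grid(n_spots, rng)
    depth = coords[:, 1] + 0.15 * np.sin(2 * np.pi * coords[:, 0])
    edges = np.quantile(depth, np.linspace(0, 1, n_domains + 1)[1:-1])
    domains = np.searchsorted(edges, depth)
    middle = frozenset(range(1, n_domains - 1)) or frozenset({0})
    cluster_domains = {1: frozenset({0}), 2: middle, 3: frozenset({n_domains - 1})}
    spot_ids = [f"s{i + 1}" for i in range(n_spots)]
    return DomainTemplate(SpatialCoords(coords, spot_ids), domains, cluster_domains)


def template_from_annotation(path: str) -> DomainTemplate:
    """Build a domain template from a real annotation table.

    Expects a delimited file with columns ``spot_id, x, y, domain``. Domains
    are relabeled 0..k-1 in sorted order; the three gene clusters map to the
    first band, the middle bands, and the last band respectively (the
    layered-tissue convention of the built-in template).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    coords = SpatialCoords(
        df.iloc[:, 1:3].to_numpy(dtype=float), df.iloc[:, 0].astype(str).tolist()
    )
    raw = df.iloc[:, 3]
    levels = sorted(raw.unique())
    domains = raw.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    k = len(levels)
    if k < 2:
        raise ValueError("annotation must contain at least two domains")
    middle = frozenset(range(1, k - 1)) or frozenset({0})
    cluster_domains = {1: frozenset({0}), 2: middle, 3: frozenset({k - 1})}
    return DomainTemplate(coords, domains, cluster_domains)


def simulate_domain_dataset(
    config: DomainSimConfig | None = None, template: DomainTemplate | None = None
) -> SimulatedDataset:
    """Simulate the domain-detection design on a layered template.

    Defaults follow the study conditions: 4865 genes x 3484 spots with 2000
    SVGs split 800/150/1050 across three domain-linked clusters.
    """
    cfg = config or DomainSimConfig()
    tpl = template or builtin_template(cfg.n_spots, cfg.n_domains, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    n = tpl.coords.n_spots
    m = cfg.n_genes

    mu = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sd, size=m)
    sd = rng.lognormal(cfg.sd_log_mu, cfg.sd_log_sd, size=m)
    svg_idx = rng.choice(m, size=sum(cfg.svg_counts), replace=False)
    gene_truth = np.array(["noise"] * m, dtype=object)
    start = 0
    for c, count in enumerate(cfg.svg_counts, start=1):
        gene_truth[svg_idx[start : start + count]] = f"cluster{c}"
        start += count

    # each SVG is overexpressed in one domain drawn from its cluster's domain
    # set: multi-domain clusters (the middle-layer cluster) spread their genes
    # across the member layers, so every domain stays identifiable while the
    # cluster remains the biological unit
    values = mu[:, None] + sd[:, None] * rng.standard_normal((m, n))
    for c in range(1, len(cfg.svg_counts) + 1):
        domain_set = sorted(tpl.cluster_domains[c])
        rows = np.where(gene_truth == f"cluster{c}")[0]
        gene_domain = rng.choice(domain_set, size=rows.size)
        for d in domain_set:
            in_d = np.where(tpl.domains == d)[0]
            sub = rows[gene_domain == d]
            values[sub[:, None], in_d[None, :]] += cfg.effect_size * sd[sub][:, None]

    gene_ids = [f"gene_{i + 1}" for i in range(m)]
    expr = ExpressionMatrix(values, gene_ids, list(tpl.coords.spot_ids), normalized=True)
    return SimulatedDataset(expr, tpl.coords, gene_truth, tpl.domains.copy())


def write_dataset(dataset: SimulatedDataset, outdir: str, format: str = "delimited") -> dict[str, str]:
    """Write a simulated dataset (expression, coordinates, truth tables) in
    the formats the pipeline consumes. Returns the written paths."""
    import os

    import pandas as pd

    from .io import write_coordinates, write_expression

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    if format == "mtx":
        expr_path = os.path.join(outdir, "matrix.mtx")
    else:
        expr_path = os.path.join(outdir, "expression.tsv")
    write_expression(dataset.expr, expr_path, format=format)
    paths["expression"] = expr_path
    coords_path = os.path.join(outdir, "coordinates.tsv")
    write_coordinates(dataset.coords, coords_path)
    paths["coordinates"] = coords_path
    gt = os.path.join(outdir, "gene_truth.tsv")
    pd.DataFrame({"gene_id": dataset.expr.gene_ids, "truth": dataset.gene_truth}).to_csv(
        gt, sep="\t", index=False
    )
    paths["gene_truth"] = gt
    if dataset.domain_truth is not None:
        dt = os.path.join(outdir, "domain_truth.tsv")
        pd.DataFrame(
            {"spot_id": dataset.coords.spot_ids, "domain": dataset.domain_truth}
        ).to_csv(dt, sep="\t", index=False)
        paths["domain_truth"] = dt
    return paths
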