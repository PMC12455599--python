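"""Step 2: related-gene selection, PC covariates, adjusted testing, the
dependency graph, and Leiden gene clustering."""

import itertools

import numpy as np
import pytest

from space_st.datatypes import ExpressionMatrix
from space_st.kernels import make_kernel_bank
from space_st.simulate import Scenario1Config, simulate_scenario1
from space_st.svg_clustering import (
    AdjustedResult,
    DependencyGraph,
    RelatedSet,
    adjusted_test,
    build_graph,
    cluster_genes,
    pc_covariates,
    select_related,
)
from space_st.svg_test import KernelEigen
from tests.conftest import expression_from


def svg_matrix(values, spot_ids):
    return expression_from(np.asarray(values, dtype=float), spot_ids)


class TestSelectRelated:
    def test_duplicated_gene_is_selected(self, rng):
        n = 120
        y = rng.standard_normal(n)
        others = rng.standard_normal((3, n))
        expr = svg_matrix(np.vstack([y, y, others]), [f"s{i}" for i in range(n)])
        rel = select_related(expr, "g1")
        assert "g2" in rel.members

    def test_independent_genes_rarely_selected(self, rng):
        n = 2000
        hits = 0
        for rep in range(20):
            local = np.random.default_rng(rep)
            expr = svg_matrix(local.standard_normal((6, n)), [f"s{i}" for i in range(n)])
            rel = select_related(expr, "g1")
            hits += bool(rel.members)
        assert hits <= 2  # empty in >= 90% of replicates

    def test_planted_partner_found(self):
        n = 2000
        found = 0
        for rep in range(20):
            local = np.random.default_rng(100 + rep)
            y = local.standard_normal(n)
            partner = 0.9 * y + np.sqrt(1 - 0.81) * local.standard_normal(n)
            others = local.standard_normal((2, n))
            expr = svg_matrix(np.vstack([y, partner, others]), [f"s{i}" for i in range(n)])
            rel = select_related(expr, "g1")
            found += rel.members == ["g2"]
        assert found >= 15  # exact partner in a clear majority of replicates

    def test_zero_variance_target_raises(self, rng):
        expr = svg_matrix(
            np.vstack([np.ones(50), rng.standard_normal(50)]), [f"s{i}" for i in range(50)]
        )
        with pytest.raises(ValueError, match="zero-variance"):
            select_related(expr, "g1")


class TestPCCovariates:
    def test_identical_genes_one_pc(self, rng):
        base = rng.standard_normal(100)
        members = np.tile(base, (5, 1))
        covs, k = pc_covariates(members)
        assert k == 1 and covs.shape == (100, 1)

    def test_three_or_fewer_members_raw(self, rng):
        members = rng.standard_normal((3, 60))
        covs, k = pc_covariates(members)
        assert k == 0
        np.testing.assert_allclose(covs, members.T)

    def test_k_from_variance_fractions(self, rng):
        """Eigenvalue fractions (0.79, 0.16, 0.05) need two components."""
        n = 4000
        rng = np.random.default_rng(7)
        scores = rng.standard_normal((n, 3)) * np.sqrt([0.79, 0.16, 0.05])
        mix, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        members = (scores @ mix[:3]).T
        covs, k = pc_covariates(members, var_threshold=0.8)
        assert k == 2
        # brute-force eigen check of the cumulative-variance rule
        X = members.T - members.T.mean(0)
        ev = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        frac = np.cumsum(ev) / ev.sum()
        assert np.searchsorted(frac, 0.8) + 1 == 2


@pytest.fixture(scope="module")
def eigens(medium_coords):
    return [KernelEigen.from_kernel(k) for k in make_kernel_bank(medium_coords)]


class TestAdjustedTest:
    def test_self_regression_degenerate(self, medium_coords, eigens, rng):
        y = rng.standard_normal(medium_coords.n_spots)
        p, _ = adjusted_test(y, y[:, None], eigens)
        assert p == 1.0

    def test_linear_combination_plus_noise_uniform(self, medium_coords, eigens):
        """When covariates fully explain the structure, the adjusted p is
        null-distributed (KS over replicates)."""
        from scipy import stats

        n = medium_coords.n_spots
        ps = []
        for rep in range(60):
            local = np.random.default_rng(rep)
            covs = local.standard_normal((n, 2))
            y = covs @ np.array([1.0, -0.5]) + local.standard_normal(n)
            p, _ = adjusted_test(y, covs, eigens)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_orthogonal_pattern_stays_significant(self, medium_coords, eigens):
        from space_st.simulate import pattern_value

        n = medium_coords.n_spots
        field = pattern_value(1, medium_coords.coords)  # broad gradient
        hits = 0
        for rep in range(20):
            local = np.random.default_rng(rep)
            covs = local.standard_normal((n, 3))  # spatially structureless
            y = 2.0 * field + local.standard_normal(n)
            p, _ = adjusted_test(y, covs, eigens)
            hits += p < 0.01
        assert hits >= 18

    def test_collinear_covariates_dropped(self, medium_coords, eigens, rng):
        n = medium_coords.n_spots
        covs = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        p, rank = adjusted_test(y, covs, eigens)
        assert rank == 2  # intercept + the one informative column
        assert 0 <= p <= 1


class TestBuildGraph:
    def test_direct_edge_rule(self):
        related = {
            "a": RelatedSet("a", ["b"], {"b": 0.8}),
            "b": RelatedSet("b", []),
            "c": RelatedSet("c", ["a"], {"a": 0.4}),
        }
        adjusted = {
            "a": AdjustedResult("a", 0, 0.9, unique_pattern=False),
            "b": AdjustedResult("b", 0, 0.9, unique_pattern=False),
            "c": AdjustedResult("c", 0, 1e-6, unique_pattern=True),
        }
        g = build_graph(["a", "b", "c"], related, adjusted)
        assert g.edges == [("a", "b", 0.8)]  # c unique: no outgoing edges

    def test_symmetric_pair_merged(self):
        related = {
            "a": RelatedSet("a", ["b"], {"b": 0.5}),
            "b": RelatedSet("b", ["a"], {"a": 0.7}),
        }
        adjusted = {
            "a": AdjustedResult("a", 0, 0.9),
            "b": AdjustedResult("b", 0, 0.9),
        }
        g = build_graph(["a", "b"], related, adjusted)
        assert g.edges == [("a", "b", 0.7)]  # max weight kept


def modularity(nodes, edges, partition):
    """Weighted Newman modularity computed from scratch."""
    m2 = 2.0 * sum(w for _, _, w in edges)
    deg = {v: 0.0 for v in nodes}
    for a, b, w in edges:
        deg[a] += w
        deg[b] += w
    q = 0.0
    for a, b, w in edges:
        if partition[a] == partition[b]:
            q += 2.0 * w / m2
    for v in nodes:
        for u in nodes:
            if partition[u] == partition[v]:
                q -= deg[u] * deg[v] / (m2 * m2)
    return q


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


class TestClusterGenes:
    def test_two_cliques(self, rng):
        nodes = list("abcdefgh")
        edges = [
            (a, b, 1.0)
            for block in (nodes[:4], nodes[4:])
            for a, b in itertools.combinations(block, 2)
        ]
        out = cluster_genes(DependencyGraph(nodes, edges), min_size=2)
        labels = out.set_index("gene_id")["cluster"]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels["a"] != labels["e"]
        assert not out["singleton"].any()

    def test_isolated_node_singleton(self):
        out = cluster_genes(DependencyGraph(["a", "b", "c"], [("a", "b", 1.0)]))
        row = out.set_index("gene_id")
        assert row.loc["c", "singleton"]
        assert row.loc["c", "cluster"] not in (row.loc["a", "cluster"],)

    def test_matches_exhaustive_modularity(self, rng):
        """Leiden at resolution 1 attains the exhaustive maximum-modularity
        partition on an 8-node weighted graph with community structure."""
        nodes = list("abcdefgh")
        local = np.random.default_rng(3)
        edges = []
        for blk in (nodes[:4], nodes[4:]):
            for a, b in itertools.combinations(blk, 2):
                edges.append((a, b, 0.6 + 0.4 * float(local.random())))
        edges += [("a", "e", 0.15), ("c", "g", 0.2)]  # weak cross-links
        out = cluster_genes(DependencyGraph(nodes, edges), seed=0)
        found = out.set_index("gene_id")["cluster"].to_dict()
        best = max(
            (
                modularity(nodes, edges, {v: i for i, blk in enumerate(p) for v in blk})
                for p in set_partitions(nodes)
            )
        )
        assert modularity(nodes, edges, found) == pytest.approx(best, abs=1e-9)

    def test_deterministic_under_seed(self, rng):
        nodes = [f"g{i}" for i in range(12)]
        local = np.random.default_rng(8)
        edges = [
            (a, b, float(local.random()) + 0.01)
            for a, b in itertools.combinations(nodes, 2)
            if local.random() < 0.4
        ]
        g = DependencyGraph(nodes, edges)
        a = cluster_genes(g, seed=7)
        b = cluster_genes(g, seed=7)
        assert a.equals(b)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            cluster_genes(DependencyGraph([], []))


def test_scenario1_within_group_edges_denser(medium_coords):
    """Pattern-group SVGs connect much more densely within their own group
    than across groups (scenario-I structure at reduced size)."""
    within_wins = 0
    for rep in range(3):
        ds = simulate_scenario1(Scenario1Config(n_spots=500, seed=300 + rep))
        from space_st.svg_test import detect_svgs
        from space_st.svg_clustering import classify_svgs

        bank = [KernelEigen.from_kernel(k) for k in make_kernel_bank(ds.coords)]
        tab = detect_svgs(ds.expr, ds.coords, bank=bank)
        clusters, graph = classify_svgs(ds.expr, tab, bank)
        truth = dict(zip(ds.expr.gene_ids, ds.gene_truth))
        within = between = 0
        for a, b, _ in graph.edges:
            if truth[a] == truth[b]:
                within += 1
            else:
                between += 1
        within_wins += within > between
    assert within_wins >= 2
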