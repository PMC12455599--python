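"""Per-cluster spatial embeddings, aggregation, and spot clustering."""

import numpy as np
import pandas as pd
import pytest

from space_st.datatypes import SpatialCoords
from space_st.domains import (
    aggregate,
    baseline_pipeline,
    cluster_spots,
    embed_cluster,
)
from space_st.metrics import ari
from space_st.simulate import _jittered_grid
from tests.conftest import expression_from


@pytest.fixture(scope="module")
def two_domain_data():
    """A cluster of genes overexpressed in the left tissue half."""
    rng = np.random.default_rng(21)
    coords = SpatialCoords(_jittered_grid(300, rng))
    left = (coords.coords[:, 0] < 0.5).astype(float)
    values = 1.5 * left[None, :] + rng.standard_normal((12, 300))
    return expression_from(values, coords.spot_ids), coords, left


class TestEmbedCluster:
    def test_default_five_components(self, two_domain_data):
        expr, coords, _ = two_domain_data
        emb = embed_cluster(expr, coords)
        assert emb.scores.shape == (300, 5)

    def test_small_cluster_truncates_with_warning(self, two_domain_data):
        expr, coords, _ = two_domain_data
        small = expr.subset_genes(expr.gene_ids[:3])
        with pytest.warns(UserWarning, match="truncating"):
            emb = embed_cluster(small, coords)
        assert emb.scores.shape[1] == 3

    def test_zero_bandwidth_limit_is_plain_pca(self, two_domain_data):
        expr, coords, _ = two_domain_data
        plain = embed_cluster(expr, coords, method="pca")
        tiny = embed_cluster(expr, coords, method="smoothed_pca", bandwidth_quantile=0.0)
        for j in range(5):
            dot = abs(np.dot(plain.scores[:, j], tiny.scores[:, j]))
            norm = np.linalg.norm(plain.scores[:, j]) * np.linalg.norm(tiny.scores[:, j])
            assert dot == pytest.approx(norm, rel=1e-2)  # equal up to column sign

    def test_first_component_separates_domains(self, two_domain_data):
        expr, coords, left = two_domain_data
        emb = embed_cluster(expr, coords)
        r = np.corrcoef(emb.scores[:, 0], left)[0, 1]
        assert abs(r) > 0.9

    def test_external_embedding_round_trip(self, tmp_path, two_domain_data):
        expr, coords, _ = two_domain_data
        ref = embed_cluster(expr, coords)
        path = tmp_path / "emb.tsv"
        pd.DataFrame(ref.scores, index=coords.spot_ids).to_csv(path, sep="\t")
        ext = embed_cluster(expr, coords, method="external", external_path=str(path))
        np.testing.assert_allclose(ext.scores, ref.scores)
        bad = pd.DataFrame(ref.scores[:100], index=coords.spot_ids[:100])
        bad.to_csv(tmp_path / "bad.tsv", sep="\t")
        with pytest.raises(ValueError, match="row count"):
            embed_cluster(expr, coords, method="external", external_path=str(tmp_path / "bad.tsv"))

    def test_rigid_motion_changes_scores_only_by_sign(self, two_domain_data):
        expr, coords, _ = two_domain_data
        t = np.deg2rad(45.0)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        moved = SpatialCoords(coords.coords @ R.T + 1.0)
        a = embed_cluster(expr, coords).scores
        b = embed_cluster(expr, moved).scores
        for j in range(a.shape[1]):
            assert abs(np.dot(a[:, j], b[:, j])) == pytest.approx(
                np.linalg.norm(a[:, j]) * np.linalg.norm(b[:, j]), rel=1e-6
            )


class TestAggregate:
    def test_width_is_sum_of_blocks(self, two_domain_data):
        expr, coords, _ = two_domain_data
        embs = [embed_cluster(expr, coords, cluster=c) for c in range(3)]
        agg = aggregate(embs)
        assert agg.scores.shape == (300, 15)
        assert agg.provenance[0] == (0, 0) and agg.provenance[-1] == (2, 4)

    def test_blocks_standardized(self, two_domain_data):
        expr, coords, _ = two_domain_data
        emb = embed_cluster(expr, coords)
        scaled = embed_cluster(expr, coords)
        scaled.scores = scaled.scores * 100.0
        agg = aggregate([emb, scaled])
        v1 = agg.scores[:, :5].var(axis=0).sum()
        v2 = agg.scores[:, 5:].var(axis=0).sum()
        assert v1 == pytest.approx(1.0) and v2 == pytest.approx(1.0)

    def test_cluster_order_does_not_change_domains(self, two_domain_data):
        expr, coords, _ = two_domain_data
        e1 = embed_cluster(expr.subset_genes(expr.gene_ids[:6]), coords, cluster=0)
        e2 = embed_cluster(expr.subset_genes(expr.gene_ids[6:]), coords, cluster=1)
        lab_a = cluster_spots(aggregate([e1, e2]), coords, mode="known_k", k_d=2)
        lab_b = cluster_spots(aggregate([e2, e1]), coords, mode="known_k", k_d=2)
        assert ari(lab_a, lab_b) == pytest.approx(1.0)


class TestClusterSpots:
    def test_two_separated_blobs_exact(self, rng):
        centers = np.array([[0.0, 0.0], [8.0, 8.0]])
        truth = np.repeat([0, 1], 100)
        emb = centers[truth] + 0.3 * rng.standard_normal((200, 2))
        labels = cluster_spots(emb, mode="known_k", k_d=2)
        assert ari(labels, truth) == 1.0

    def test_identical_rows_single_domain(self):
        emb = np.ones((50, 3))
        labels = cluster_spots(emb, mode="unknown_k")
        assert len(np.unique(labels)) == 1

    def test_deterministic_at_fixed_seed(self, rng):
        emb = rng.standard_normal((120, 4))
        a = cluster_spots(emb, mode="unknown_k", seed=3)
        b = cluster_spots(emb, mode="unknown_k", seed=3)
        np.testing.assert_array_equal(a, b)

    def test_labels_contiguous_from_zero(self, rng):
        emb = rng.standard_normal((100, 3))
        labels = cluster_spots(emb, mode="unknown_k")
        assert labels.min() == 0
        assert set(np.unique(labels)) == set(range(labels.max() + 1))

    def test_known_k_requires_kd(self, rng):
        with pytest.raises(ValueError, match="k_d"):
            cluster_spots(rng.standard_normal((50, 2)), mode="known_k")

    @pytest.mark.parametrize("method", ["louvain", "walktrap"])
    def test_alternative_methods_run(self, rng, method):
        centers = np.array([[0.0, 0.0], [8.0, 8.0]])
        truth = np.repeat([0, 1], 60)
        emb = centers[truth] + 0.3 * rng.standard_normal((120, 2))
        labels = cluster_spots(emb, mode="known_k", k_d=2, method=method)
        assert ari(labels, truth) == 1.0


class TestBaseline:
    def test_embedding_width_and_truncation(self, two_domain_data, rng):
        expr, coords, left = two_domain_data
        svg_table = pd.DataFrame(
            {
                "gene_id": expr.gene_ids,
                "p_combined": np.linspace(1e-6, 1e-3, expr.n_genes),
                "is_svg": True,
            }
        )
        with pytest.warns(UserWarning, match="using all"):
            labels = baseline_pipeline(
                expr, coords, svg_table, n_top_svgs=3000, n_pcs=6, mode="known_k", k_d=2
            )
        assert ari(labels, left.astype(int)) > 0.8
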