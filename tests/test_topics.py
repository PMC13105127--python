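import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from spatialtx import synth, topics
from spatialtx.errors import ValidationError
from spatialtx.topics import (
    SpatialFeatureBlock,
    choose_k_from_curve,
    classify_topics,
    clr_normalize,
    concat_spatial,
    encode_spatial_features,
    fit_lda,
    tokenize_clr,
)

from conftest import make_dataset


class TestCLR:
    def test_identical_counts_row_is_zero(self):
        clr = clr_normalize(np.array([[4, 4, 4, 4]]))
        np.testing.assert_allclose(clr, 0.0, atol=1e-12)

    def test_arithmetic_example(self):
        clr = clr_normalize(np.array([[0.0, 0.0, np.e - 1.0]]), pseudocount=1.0)
        np.testing.assert_allclose(clr[0], [-1 / 3, -1 / 3, 2 / 3], atol=1e-12)

    def test_rows_zero_mean(self, toy_dataset):
        clr = clr_normalize(toy_dataset)
        np.testing.assert_allclose(clr.mean(axis=1), 0.0, atol=1e-12)

    def test_bad_pseudocount(self):
        with pytest.raises(ValidationError):
            clr_normalize(np.ones((2, 2)), pseudocount=0.0)


class TestTokenize:
    def test_negative_clips_to_zero(self):
        assert tokenize_clr(np.array([[-0.7, 0.0]]))[0, 0] == 0

    def test_half_up_rounding(self):
        toks = tokenize_clr(np.array([[0.84, 0.05, 0.25]]))
        assert toks.tolist() == [[8, 1, 3]]  # 8.4->8, 0.5->1, 2.5->3

    def test_all_negative_row_has_no_tokens(self):
        toks = tokenize_clr(np.array([[-1.0, -2.0], [1.0, 0.5]]))
        assert toks[0].sum() == 0


class TestFitLDA:
    def test_simplex_and_determinism(self):
        rng = np.random.default_rng(0)
        tokens = rng.integers(0, 5, size=(40, 30))
        r1 = fit_lda(tokens, 3, iterations=60, burnin=30, seed=9)
        r2 = fit_lda(tokens, 3, iterations=60, burnin=30, seed=9)
        np.testing.assert_allclose(r1.cell_topic.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(r1.feature_topic.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_array_equal(r1.cell_topic, r2.cell_topic)
        np.testing.assert_array_equal(r1.feature_topic, r2.feature_topic)

    def test_too_many_topics_rejected(self):
        with pytest.raises(ValidationError):
            fit_lda(np.ones((5, 4), dtype=int), 4)

    def test_empty_cells_get_uniform_prior_row(self):
        tokens = np.array([[0, 0, 0, 0, 0], [3, 1, 0, 2, 1], [1, 1, 1, 4, 0]])
        res = fit_lda(tokens, 2, iterations=20, burnin=10, seed=0)
        np.testing.assert_allclose(res.cell_topic[0], 0.5)
        assert res.excluded_cells.tolist() == [0]

    def test_planted_topic_recovery_small(self):
        cfg = synth.topic_benchmark_config(n_cells=600, n_genes=150, block_genes=40, seed=3)
        ds, truth = synth.simulate_dataset(cfg)
        tokens = tokenize_clr(clr_normalize(ds))
        res = fit_lda(tokens, 3, iterations=150, burnin=75, seed=7)
        truth_mix = truth[[f"topic_{k}" for k in range(3)]].to_numpy()
        a = res.cell_topic / np.linalg.norm(res.cell_topic, axis=0)
        b = truth_mix / np.linalg.norm(truth_mix, axis=0)
        sim = a.T @ b
        rows, cols = linear_sum_assignment(-sim)
        assert sim[rows, cols].mean() >= 0.9


class TestElbowRule:
    def test_injected_curve(self):
        k, degenerate = choose_k_from_curve([10, 20, 30, 40, 50], [100, 60, 40, 35, 33])
        assert (k, degenerate) == (20, False)

    def test_linear_curve_degenerate(self):
        k, degenerate = choose_k_from_curve([10, 20, 30, 40], [100, 80, 60, 40])
        assert (k, degenerate) == (10, True)

    def test_tie_prefers_smaller_k(self):
        # second differences at K=20 and K=30 both equal 10
        k, _ = choose_k_from_curve([10, 20, 30, 40], [100, 70, 50, 40])
        assert k == 20

    def test_too_few_candidates(self):
        with pytest.raises(ValidationError):
            choose_k_from_curve([10, 20], [5, 4])

    def test_select_topic_number_runs(self):
        rng = np.random.default_rng(1)
        # two obvious word blocks
        tokens = np.zeros((60, 20), dtype=int)
        tokens[:30, :10] = rng.integers(1, 5, size=(30, 10))
        tokens[30:, 10:] = rng.integers(1, 5, size=(30, 10))
        k_star, curve = topics.select_topic_number(
            tokens, candidates=[2, 3, 4, 5], iterations=40, burnin=20, seed=0
        )
        assert k_star in (2, 3, 4, 5)
        assert len(curve) == 4
        assert all(p > 0 for _, p in curve)


def _grid_dataset(n=300, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(2, size=(n, 5))
    return make_dataset(
        counts, x=rng.uniform(0, 1000, n), y=rng.uniform(0, 1000, n)
    )


class TestSpatialEncoding:
    def test_default_nonzero_count(self):
        ds = _grid_dataset()
        block = encode_spatial_features(ds, k_centroids=200, seed=0)
        nnz = (block.cell_features > 0).sum(axis=1)
        assert (nnz == 10).all()  # ceil(0.05 * 200)

    def test_coincident_cell_reaches_global_max(self):
        ds = _grid_dataset(n=250)
        block = encode_spatial_features(ds, k_centroids=20, top_fraction=0.1, scale=1.0, seed=0)
        coords = np.column_stack([ds.x, ds.y])
        d = np.linalg.norm(coords[:, None] - block.centroids[None], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        # proximity of the overall closest cell-centroid pair approaches D_max
        assert block.cell_features[i, j] == pytest.approx(d.max() - d.min())

    def test_translation_invariance(self):
        ds = _grid_dataset()
        block = encode_spatial_features(ds, k_centroids=50, seed=1)
        ds_shift = make_dataset(
            np.asarray(ds.counts.todense()), x=ds.x + 500.0, y=ds.y - 250.0
        )
        block_shift = encode_spatial_features(ds_shift, k_centroids=50, seed=1)
        np.testing.assert_allclose(
            block.cell_features, block_shift.cell_features, atol=1e-6
        )

    def test_too_many_centroids(self):
        with pytest.raises(ValidationError):
            encode_spatial_features(_grid_dataset(n=50), k_centroids=60)


class TestConcatAndClassify:
    def test_concat_shapes_and_provenance(self):
        tokens = np.ones((30, 12), dtype=int)
        block = SpatialFeatureBlock(
            centroids=np.zeros((4, 2)),
            cell_features=np.zeros((30, 4)),
            k_centroids=4,
            top_fraction=0.25,
            scale=10.0,
        )
        aug, prov = concat_spatial(tokens, block)
        assert aug.shape == (30, 16)
        assert (prov == "centroid").sum() == 4

    def test_cell_mismatch(self):
        block = SpatialFeatureBlock(
            centroids=np.zeros((4, 2)),
            cell_features=np.zeros((10, 4)),
            k_centroids=4,
            top_fraction=0.25,
            scale=10.0,
        )
        with pytest.raises(ValidationError):
            concat_spatial(np.ones((9, 3), dtype=int), block)

    def test_zero_block_reproduces_gene_only_fit(self):
        rng = np.random.default_rng(2)
        tokens = rng.integers(0, 4, size=(50, 25))
        block = SpatialFeatureBlock(
            centroids=np.zeros((8, 2)),
            cell_features=np.zeros((50, 8)),
            k_centroids=8,
            top_fraction=0.25,
            scale=10.0,
        )
        aug, _ = concat_spatial(tokens, block)
        base = fit_lda(tokens, 3, iterations=60, burnin=30, seed=4)
        spat = fit_lda(aug, 3, iterations=60, burnin=30, seed=4)
        np.testing.assert_array_equal(base.cell_topic, spat.cell_topic)
        np.testing.assert_array_equal(base.feature_topic, spat.feature_topic[:25])
        assert np.all(spat.feature_topic[25:] == 0)

    def _result_with_top_features(self, n_centroid_in_top):
        # 30 genes + 20 centroid features, one topic per case
        n_feat = 50
        weights = np.full((n_feat, 2), 1e-6)
        top = list(range(30))[: 20 - n_centroid_in_top] + [
            30 + i for i in range(n_centroid_in_top)
        ]
        weights[top, 0] = 1.0
        weights[:, 1] = np.linspace(1, 2, n_feat)
        weights /= weights.sum(axis=0, keepdims=True)
        prov = np.array(["gene"] * 30 + ["centroid"] * 20, dtype=object)
        res = topics.TopicModelResult(
            cell_topic=np.full((3, 2), 0.5),
            feature_topic=weights,
            n_topics=2,
            params={},
            excluded_cells=np.array([], dtype=int),
            zero_features=np.array([], dtype=int),
        )
        return res, prov

    def test_gene_restricted(self):
        res, prov = self._result_with_top_features(0)
        assert classify_topics(res, prov)[0] == "gene_restricted"

    def test_spatial_restricted(self):
        res, prov = self._result_with_top_features(17)  # 17/20 = 0.85 >= 0.8
        assert classify_topics(res, prov)[0] == "spatial_restricted"

    def test_spatially_integrated(self):
        res, prov = self._result_with_top_features(5)
        assert classify_topics(res, prov)[0] == "spatially_integrated"
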