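"""Feature partitioning, reduced multinomial fits, and the sparse C matrix."""

import numpy as np
import pytest

from sraselect import (
    PerformanceMatrix,
    build_performance_matrix,
    cross_entropy,
    fit_all_blocks,
    fit_block_model,
    partition_features,
)
from sraselect.reduced import MultinomialLogit
from conftest import make_dataset


class TestPartition:
    def test_single_block_is_permutation(self):
        part = partition_features(10, 10, seed=0)
        assert part.n_blocks == 1
        assert sorted(part.blocks[0]) == list(range(10))

    def test_include_remainder_covers_everything(self):
        part = partition_features(1000, 250, seed=1, drop_remainder=False)
        assert part.n_blocks == 4
        union = set()
        for b in part.blocks:
            assert not union & set(b.tolist())
            union |= set(b.tolist())
        assert union == set(range(1000))

    def test_drop_remainder_discards_tail(self):
        part = partition_features(1001, 250, seed=1, drop_remainder=True)
        assert part.n_blocks == 4
        assert sum(len(b) for b in part.blocks) == 1000

    def test_invalid_block_size(self):
        with pytest.raises(ValueError):
            partition_features(10, 11, seed=0)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        probs = np.eye(3)[[0, 1, 2, 0]]
        assert cross_entropy([0, 1, 2, 0], probs) == pytest.approx(0.0, abs=1e-10)

    def test_coin_flip_is_ln2(self):
        probs = np.full((2, 2), 0.5)
        assert cross_entropy([0, 1], probs) == pytest.approx(np.log(2), abs=1e-12)

    def test_uniform_five_way_is_ln5(self):
        probs = np.full((4, 5), 0.2)
        assert cross_entropy([0, 1, 2, 3], probs) == pytest.approx(np.log(5), abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            cross_entropy([0, 1, 0], np.full((2, 2), 0.5))


class TestBlockModel:
    def test_constant_snps_give_intercept_only_entropy(self):
        # all-constant features: probabilities collapse to class frequencies,
        # so CE = -sum_b (g_b/N) ln(g_b/N); 5 balanced classes -> ln 5
        n_per = 6
        labels = np.repeat([f"c{i}" for i in range(5)], n_per)
        dos = np.ones((5 * n_per, 3), dtype=np.int8)
        ds = make_dataset(dos, labels=labels)
        fit = fit_block_model(ds, np.arange(3), ridge=1e-6)
        assert np.abs(fit.beta_hat).max() < 1e-4
        assert fit.ce_loss == pytest.approx(np.log(5), abs=1e-3)

    def test_perfectly_separating_snp_reaches_tiny_loss(self):
        dos = np.array([[0], [0], [0], [0], [2], [2], [2], [2]], dtype=np.int8)
        ds = make_dataset(dos, labels=["a"] * 4 + ["b"] * 4)
        fit = fit_block_model(ds, np.array([0]), ridge=1e-6)
        assert fit.ce_loss < 0.01

    def test_two_class_fit_matches_sklearn_oracle(self):
        # identical penalty: our mean-scale ridge r equals sklearn C = 1/(N r)
        from sklearn.linear_model import LogisticRegression

        x = np.array([0, 0, 1, 1, 1, 2, 2, 2], dtype=float)[:, None]
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        ridge = 1e-2
        ours = MultinomialLogit(ridge=ridge, gtol=1e-10).fit(x, y)
        ref = LogisticRegression(
            C=1.0 / (len(y) * ridge), tol=1e-10, max_iter=10_000
        ).fit(x, y)
        # our model parameterises log(P_first / P_last); sklearn binary gives
        # log(P_second / P_first) -> negate
        assert ours.beta_[0, 0] == pytest.approx(-ref.coef_[0, 0], abs=1e-4)
        assert ours.alpha_[0] == pytest.approx(-ref.intercept_[0], abs=1e-4)

    def test_ce_invariant_to_snp_order(self, small_sim):
        ds, _ = small_sim
        block = np.arange(12)
        a = fit_block_model(ds, block)
        b = fit_block_model(ds, block[::-1].copy())
        assert a.ce_loss == pytest.approx(b.ce_loss, rel=1e-6)

    def test_fit_invariant_to_individual_permutation(self, small_sim):
        ds, _ = small_sim
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        a = fit_block_model(ds, np.arange(8))
        b = fit_block_model(ds.subset_samples(perm), np.arange(8))
        np.testing.assert_allclose(a.beta_hat, b.beta_hat, atol=1e-5)
        assert a.ce_loss == pytest.approx(b.ce_loss, rel=1e-6)

    def test_single_class_raises(self):
        ds = make_dataset(np.zeros((4, 2), dtype=np.int8), labels=["x"] * 4)
        with pytest.raises(ValueError):
            fit_block_model(ds, np.arange(2))


class TestPerformanceMatrix:
    def _toy_fits(self, small_sim):
        ds, _ = small_sim
        part = partition_features(ds.n_snps, 50, seed=4)
        return fit_all_blocks(ds, part), part

    def test_sparse_bookkeeping(self, small_sim):
        ds, _ = small_sim
        part = partition_features(6, 3, seed=0)
        sub = ds.subset_snps(np.arange(6))
        c = fit_all_blocks(sub, part)
        assert c.n_rows == 2
        assert sum(len(ix) for ix in c.row_snp_indices) == 6
        assert len(c.ce_loss) == 2

    def test_unscored_snp_defaults_to_zero(self, small_sim):
        ds, _ = small_sim
        part = partition_features(ds.n_snps, 70, seed=0, drop_remainder=True)
        c = fit_all_blocks(ds, part)
        scored = np.concatenate(c.row_snp_indices)
        unscored = np.setdiff1d(np.arange(ds.n_snps), scored)
        assert len(unscored) == ds.n_snps % 70
        dense = c.to_dense()
        assert np.all(dense[:, unscored] == 0)

    def test_dense_assembly_matches_brute_force(self, small_sim):
        c, part = self._toy_fits(small_sim)
        dense = c.to_dense()
        p = c.p_total
        brute = np.zeros((c.n_rows, p + 1))
        for k, (ix, fp) in enumerate(zip(c.row_snp_indices, c.row_fp_values)):
            for j, v in zip(ix, fp):
                brute[k, j] = v
            brute[k, p] = c.ce_loss[k]
        np.testing.assert_array_equal(dense, brute)

    def test_each_snp_scored_once(self, small_sim):
        c, _ = self._toy_fits(small_sim)
        scored = np.concatenate(c.row_snp_indices)
        assert len(scored) == len(set(scored.tolist()))

    def test_duplicate_block_raises(self, small_sim):
        ds, _ = small_sim
        part = partition_features(ds.n_snps, 150, seed=0)
        fits = [fit_block_model(ds, part.blocks[0], block_index=0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_performance_matrix(fits, part)

    def test_hdf5_round_trip(self, small_sim, tmp_path):
        c, _ = self._toy_fits(small_sim)
        path = tmp_path / "c.h5"
        c.save(str(path))
        back = PerformanceMatrix.load(str(path))
        np.testing.assert_allclose(back.ce_loss, c.ce_loss)
        np.testing.assert_array_equal(
            np.concatenate(back.row_snp_indices), np.concatenate(c.row_snp_indices)
        )
        np.testing.assert_allclose(back.to_dense(), c.to_dense())

    def test_storage_is_o_ks(self, small_sim):
        # the sparse store keeps K*S FP entries + K losses, never K*P
        c, part = self._toy_fits(small_sim)
        stored = sum(len(v) for v in c.row_fp_values) + len(c.ce_loss)
        assert stored == c.n_rows * 50 + c.n_rows
        assert stored < c.n_rows * c.p_total
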