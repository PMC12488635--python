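"""Labeling, feature assembly, normalization, resampling and fold splitting."""

from collections import Counter

import numpy as np
import pytest

from phagegate import (InteractionMatrix, PairDataset, apply_minmax,
                       assemble_pair, binarize_labels, fit_minmax, oversample,
                       split_stratified_folds, undersample)


def make_matrix(scores):
    scores = np.asarray(scores, dtype=float)
    return InteractionMatrix(
        host_ids=tuple(f"h{i}" for i in range(scores.shape[0])),
        phage_ids=tuple(f"p{j}" for j in range(scores.shape[1])),
        scores=scores,
    )


def make_dataset(labels, rng, s=3, d=4):
    labels = np.asarray(labels)
    n = len(labels)
    return PairDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        stats=rng.normal(size=(n, s)),
        expert1=rng.normal(size=(n, d)),
        expert2=rng.normal(size=(n, d)),
        labels=labels,
    )


class TestBinarize:
    @pytest.mark.parametrize("score,label", [(1.6, 1), (1.4, 0), (1.5, 0)])
    def test_threshold_rule_is_strict_greater(self, score, label):
        triples, _ = binarize_labels(make_matrix([[score]]))
        assert triples == [("h0", "p0", label)]

    def test_missing_cells_skipped_and_counted(self):
        triples, n_missing = binarize_labels(make_matrix([[2.0, np.nan], [1.0, np.nan]]))
        assert len(triples) == 2 and n_missing == 2

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no measured"):
            binarize_labels(make_matrix([[np.nan, np.nan]]))


class TestAssemblePair:
    def test_mean_is_idempotent_on_identical_vectors(self, rng):
        v = rng.normal(size=5)
        np.testing.assert_array_equal(assemble_pair(v, v, "mean"), v)

    def test_mean_of_opposites_is_zero(self, rng):
        v = rng.normal(size=5)
        np.testing.assert_allclose(assemble_pair(v, -v, "mean"), np.zeros(5))

    def test_concat_doubles_width(self, rng):
        out = assemble_pair(rng.normal(size=26), rng.normal(size=26), "concat")
        assert out.shape == (52,)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            assemble_pair(rng.normal(size=4), rng.normal(size=5), "mean")


class TestMinMax:
    def test_linear_map(self):
        X = np.array([[0.0], [5.0], [10.0]])
        out = apply_minmax(X, fit_minmax(X))
        np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        X = np.full((4, 2), 7.0)
        assert np.all(apply_minmax(X, fit_minmax(X)) == 0.0)

    def test_out_of_range_values_not_clipped(self):
        params = fit_minmax(np.array([[0.0], [1.0]]))
        out = apply_minmax(np.array([[2.0], [-1.0]]), params)
        np.testing.assert_allclose(out[:, 0], [2.0, -1.0])

    def test_column_scan_oracle(self, rng):
        X = rng.normal(size=(30, 6))
        out = apply_minmax(X, fit_minmax(X))
        for j in range(X.shape[1]):
            assert out[np.argmin(X[:, j]), j] == 0.0
            assert out[np.argmax(X[:, j]), j] == pytest.approx(1.0)
        assert np.all((out >= 0) & (out <= 1))

    def test_empty_fit_set_rejected(self):
        with pytest.raises(ValueError):
            fit_minmax(np.empty((0, 3)))


class TestResampling:
    def test_oversample_equalizes_counts(self, rng):
        ds = make_dataset([1] * 3 + [0] * 7, rng)
        out = oversample(ds, seed=0)
        assert Counter(out.labels.tolist()) == {0: 7, 1: 7}

    def test_undersample_equalizes_counts(self, rng):
        ds = make_dataset([1] * 3 + [0] * 7, rng)
        out = undersample(ds, seed=0)
        assert Counter(out.labels.tolist()) == {0: 3, 1: 3}

    def test_balanced_input_unchanged(self, rng):
        ds = make_dataset([0, 1] * 5, rng)
        assert oversample(ds, 0).sample_ids == ds.sample_ids
        assert undersample(ds, 0).sample_ids == ds.sample_ids

    def test_oversample_adds_only_minority_duplicates(self, rng):
        """Multiset difference of output vs input is all minority-class copies."""
        ds = make_dataset([1] * 4 + [0] * 9, rng)
        out = oversample(ds, seed=1)
        added = Counter(out.sample_ids) - Counter(ds.sample_ids)
        minority_ids = {sid for sid, lab in zip(ds.sample_ids, ds.labels) if lab == 1}
        assert sum(added.values()) == 5
        assert set(added) <= minority_ids
        # majority untouched
        assert Counter(s for s, l in zip(out.sample_ids, out.labels) if l == 0) \
            == Counter(s for s, l in zip(ds.sample_ids, ds.labels) if l == 0)

    def test_undersample_output_is_subset(self, rng):
        ds = make_dataset([1] * 4 + [0] * 9, rng)
        out = undersample(ds, seed=1)
        assert not Counter(out.sample_ids) - Counter(ds.sample_ids)

    @pytest.mark.parametrize("op", [oversample, undersample])
    def test_single_class_rejected(self, op, rng):
        with pytest.raises(ValueError, match="both classes"):
            op(make_dataset([1] * 5, rng), seed=0)


class TestStratifiedFolds:
    def test_balanced_example_fold_counts(self):
        labels = np.array([1] * 10 + [0] * 10)
        folds = split_stratified_folds(labels, k=5, seed=0)
        for _, test_idx in folds:
            counts = Counter(labels[test_idx].tolist())
            assert counts == {0: 2, 1: 2}

    def test_folds_partition_all_samples(self, rng):
        labels = (rng.random(37) < 0.4).astype(int)
        folds = split_stratified_folds(labels, k=4, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(37))
        for tr, te in folds:
            assert not set(tr) & set(te)

    def test_class_ratio_preserved_within_one_sample(self, rng):
        labels = (rng.random(53) < 0.3).astype(int)
        k = 5
        n_pos = labels.sum()
        for _, te in split_stratified_folds(labels, k=k, seed=2):
            pos_in_fold = labels[te].sum()
            assert abs(pos_in_fold - n_pos / k) <= 1

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer than k"):
            split_stratified_folds(labels, k=3, seed=0)


class TestDatasetContainer:
    def test_mismatched_expert_widths_rejected(self, rng):
        with pytest.raises(ValueError, match="share one width"):
            PairDataset(
                sample_ids=["a", "b"],
                stats=rng.normal(size=(2, 3)),
                expert1=rng.normal(size=(2, 4)),
                expert2=rng.normal(size=(2, 5)),
                labels=np.array([0, 1]),
            )

    def test_matrix_csv_round_trip_preserves_missing(self, tmp_path):
        m = make_matrix([[2.0, np.nan], [1.0, 1.7]])
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = InteractionMatrix.from_csv(path)
        assert np.isnan(back.scores[0, 1])
        np.testing.assert_allclose(back.scores[1], [1.0, 1.7])
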