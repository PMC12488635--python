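"""Prediction head: architecture contract, loss, joint training, inference."""

import numpy as np
import pytest

from phagegate import ModelConfig, MoEClassifier, cross_entropy, softmax
from phagegate.classifier import _loss_and_dlogits, build_cnn
from phagegate.gating import gate_forward
from phagegate.simulate import gen_separable_dataset


def tiny_config(**kw):
    base = dict(channels=(4,), fc_width=8, dropout=0.0, epochs=5,
                batch_size=16, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestBuildModel:
    def test_default_width_yields_two_logits(self, rng):
        model = MoEClassifier(s=26, d=1024, config=ModelConfig(seed=0))
        logits = model.forward(rng.random((3, 26)), rng.random((3, 1024)),
                               rng.random((3, 1024)), train=False)[2]
        assert logits.shape == (3, 2)

    def test_toy_width_builds_and_runs(self, rng):
        model = MoEClassifier(s=3, d=8, config=tiny_config())
        logits = model.forward(rng.random((2, 3)), rng.random((2, 8)),
                               rng.random((2, 8)), train=False)[2]
        assert logits.shape == (2, 2)

    def test_parameter_count_matches_hand_formula(self):
        cfg = tiny_config()
        cnn = build_cnn(cfg, input_width=11, rng=np.random.default_rng(0))
        c, k, fc = 4, cfg.kernel_size, cfg.fc_width
        expected = (c * 1 * k + c) + 2 * c + (c * fc + fc) + (fc * 2 + 2)
        assert cnn.n_parameters() == expected

    def test_pooling_stack_too_deep_names_stage(self):
        cfg = ModelConfig(channels=(4, 4, 4), dropout=0.0, seed=0)
        with pytest.raises(ValueError, match="conv block 3"):
            build_cnn(cfg, input_width=5, rng=np.random.default_rng(0))

    def test_width_below_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_cnn(tiny_config(), input_width=2, rng=np.random.default_rng(0))


class TestCrossEntropy:
    def test_uninformative_prediction_costs_ln2(self):
        assert cross_entropy(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2))

    def test_perfect_confident_predictions_near_zero(self):
        y = np.array([1.0, 0.0])
        assert cross_entropy(y, np.array([1.0 - 1e-9, 1e-9])) < 1e-6

    def test_matches_per_sample_summation_oracle(self, rng):
        y = (rng.random(40) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, size=40)
        oracle = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                           for yi, pi in zip(y, p)])
        assert cross_entropy(y, p) == pytest.approx(oracle)

    def test_equivalent_to_log_softmax_form_away_from_clamp(self, rng):
        logits = rng.normal(size=(50, 2)) * 3
        y = (rng.random(50) < 0.5).astype(int)
        loss_prob = cross_entropy(y, softmax(logits)[:, 1])
        shifted = logits - logits.max(axis=1, keepdims=True)
        log_p = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        loss_logits = -np.mean(np.where(y == 1, log_p[:, 1], log_p[:, 0]))
        assert loss_prob == pytest.approx(loss_logits, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy(np.zeros(3), np.full(4, 0.5))


class TestJointGradients:
    def test_full_model_gradient_matches_finite_differences(self, rng):
        """End-to-end analytic gradient (CNN + fusion + gate) vs central
        differences on a dropout-free, batch-norm-frozen double-precision
        graph."""
        model = MoEClassifier(s=3, d=6, config=tiny_config(batch_size=8))
        stats = rng.random((8, 3))
        e1, e2 = rng.normal(size=(8, 6)), rng.normal(size=(8, 6))
        y = (rng.random(8) < 0.5).astype(int)

        def total_loss():
            _, _, logits = model.forward(stats, e1, e2, train=True)
            return _loss_and_dlogits(y, logits)[0]

        gate_out, _, logits = model.forward(stats, e1, e2, train=True)
        loss, dlogits = _loss_and_dlogits(y, logits)
        dcombined = model.cnn.backward(dlogits)[:, 0, :]
        dfused = dcombined[:, :6]
        from phagegate.gating import gate_backward
        dalpha = np.stack([(dfused * e1).sum(1), (dfused * e2).sum(1)], axis=1)
        ggrads = gate_backward(model.gate, stats, gate_out, dalpha)

        eps = 1e-6
        arrays = list(zip(model.cnn.params, model.cnn.grads)) + [
            (model.gate.W1, ggrads["W1"]), (model.gate.b2, ggrads["b2"])]
        checked = 0
        for arr, grad in arrays:
            flat, gflat = arr.ravel(), grad.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = total_loss()
                flat[idx] = orig - eps
                down = total_loss()
                flat[idx] = orig
                assert gflat[idx] == pytest.approx((up - down) / (2 * eps), abs=2e-5)
                checked += 1
        assert checked >= 10


class TestTraining:
    def test_loss_decreases_and_learns_separable_set(self, toy_model_config):
        ds = gen_separable_dataset(n=120, s=4, d=8, seed=1)
        model = MoEClassifier(s=4, d=8, config=toy_model_config)
        hist = model.fit(ds.stats, ds.expert1, ds.expert2, ds.labels)
        assert hist[4] < hist[0]
        recs = model.predict(ds.stats, ds.expert1, ds.expert2)
        acc = np.mean([r.y_hat for r in recs] == ds.labels)
        assert acc >= 0.95

    def test_same_seed_identical_trajectories(self):
        ds = gen_separable_dataset(n=60, s=4, d=8, seed=2)
        runs = []
        for _ in range(2):
            m = MoEClassifier(s=4, d=8, config=tiny_config(epochs=4))
            runs.append(m.fit(ds.stats, ds.expert1, ds.expert2, ds.labels))
        assert runs[0] == runs[1]

    def test_frozen_gate_keeps_alpha_joint_training_moves_it(self):
        ds = gen_separable_dataset(n=60, s=4, d=8, seed=3)
        for freeze, should_move in [(True, False), (False, True)]:
            m = MoEClassifier(s=4, d=8, config=tiny_config(epochs=4))
            before = gate_forward(m.gate, ds.stats).alpha.copy()
            m.fit(ds.stats, ds.expert1, ds.expert2, ds.labels, freeze_gate=freeze)
            after = gate_forward(m.gate, ds.stats).alpha
            assert np.array_equal(before, after) is (not should_move)

    def test_single_class_training_rejected(self, rng):
        m = MoEClassifier(s=3, d=6, config=tiny_config())
        with pytest.raises(ValueError, match="both classes"):
            m.fit(rng.random((10, 3)), rng.random((10, 6)),
                  rng.random((10, 6)), np.ones(10, dtype=int))

    def test_non_finite_loss_aborts_with_diagnostic(self, rng):
        m = MoEClassifier(s=3, d=6, config=tiny_config(learning_rate=1e-3))
        stats = rng.random((10, 3))
        e1 = rng.random((10, 6))
        e1[0, 0] = np.inf
        with np.errstate(invalid="ignore"), \
                pytest.raises(RuntimeError, match="non-finite loss"):
            m.fit(stats, e1, rng.random((10, 6)),
                  np.array([0, 1] * 5))


class TestPrediction:
    def test_probabilities_sum_to_one_and_threshold_rule(self, rng):
        m = MoEClassifier(s=3, d=6, config=tiny_config())
        recs = m.predict(rng.random((20, 3)), rng.random((20, 6)),
                         rng.random((20, 6)))
        for r in recs:
            p0 = 1.0 - r.p_hat
            np.testing.assert_allclose(
                softmax(np.array([[r.z0, r.z1]]))[0], [p0, r.p_hat], atol=1e-12)
            assert r.y_hat == (1 if r.p_hat >= 0.5 else 0)

    def test_equal_logits_give_half_probability_positive_call(self):
        p = softmax(np.array([[3.0, 3.0]]))[0, 1]
        assert p == 0.5
        # the 0.5 boundary is called positive
        assert int(p >= 0.5) == 1

    def test_batch_and_single_prediction_identical(self, rng):
        ds = gen_separable_dataset(n=30, s=4, d=8, seed=5)
        m = MoEClassifier(s=4, d=8, config=tiny_config(epochs=2))
        m.fit(ds.stats, ds.expert1, ds.expert2, ds.labels)
        batch = m.predict(ds.stats, ds.expert1, ds.expert2)
        for i in rng.choice(30, size=5, replace=False):
            single = m.predict(ds.stats[i], ds.expert1[i], ds.expert2[i])[0]
            assert single.p_hat == batch[i].p_hat

    def test_width_mismatch_vs_model_rejected(self, rng):
        m = MoEClassifier(s=3, d=6, config=tiny_config())
        with pytest.raises(ValueError, match="expert widths"):
            m.predict(rng.random((2, 3)), rng.random((2, 7)), rng.random((2, 7)))


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        ds = gen_separable_dataset(n=40, s=4, d=8, seed=6)
        m = MoEClassifier(s=4, d=8, config=tiny_config(epochs=3))
        m.fit(ds.stats, ds.expert1, ds.expert2, ds.labels)
        before = [r.p_hat for r in m.predict(ds.stats, ds.expert1, ds.expert2)]
        path = tmp_path / "model.npz"
        m.save(path, extra_meta={"note": "test"})
        loaded, meta = MoEClassifier.load(path)
        after = [r.p_hat for r in loaded.predict(ds.stats, ds.expert1, ds.expert2)]
        assert before == after
        assert meta["s"] == 4 and meta["d"] == 8 and meta["note"] == "test"
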