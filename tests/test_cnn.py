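import numpy as np
import pytest

from swdeeg.cnn import (CNNConfig, CNNError, ConvNet, build_model,
                        conv_out_len, make_splits, pool_out_len, train)


class TestDimensionArithmetic:
    @pytest.mark.parametrize("n_in,k,expected", [(128, 8, 121), (256, 8, 249),
                                                 (8, 8, 1)])
    def test_conv_lengths(self, n_in, k, expected):
        assert conv_out_len(n_in, k) == expected

    @pytest.mark.parametrize("n_in,expected", [(121, 60), (249, 124), (3, 1)])
    def test_pool_lengths(self, n_in, expected):
        assert pool_out_len(n_in, 3, 2) == expected

    def test_invalid_sizes_rejected(self):
        with pytest.raises(CNNError):
            conv_out_len(4, 8)
        with pytest.raises(CNNError):
            pool_out_len(2, 3, 2)

    def test_model_shape_chain_matches_default_geometry(self):
        model = build_model(CNNConfig(), 256, 128, 3)
        assert (model.hc, model.wc) == (249, 121)
        assert (model.hp, model.wp) == (124, 60)


class TestForward:
    def test_softmax_outputs_normalized(self, rng):
        model = build_model(CNNConfig(n_classes=2, seed=0), 32, 24, 3)
        X = rng.standard_normal((6, 3, 32, 24))
        proba = model.predict_proba(X)
        assert proba.shape == (6, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(proba >= 0)

    def test_plane_dimension_preserved_through_conv_and_pool(self, rng):
        model = build_model(CNNConfig(seed=0), 64, 32, 3)
        X = rng.standard_normal((2, 3, 64, 32)).astype(np.float32)
        _, (cols, conv, A, pooled, flat) = model.forward(X, want_cache=True)
        assert conv.shape[1] == 3 and pooled.shape[1] == 3
        assert conv.shape[-2:] == (model.hc, model.wc)
        assert pooled.shape[-2:] == (model.hp, model.wp)

    def test_shape_mismatch_reports_expected_and_actual(self, rng):
        model = build_model(CNNConfig(seed=0), 64, 32, 3)
        with pytest.raises(CNNError, match="expected input"):
            model.forward(rng.standard_normal((2, 3, 64, 30)))

    def test_conv_matches_direct_computation(self, rng):
        # GEMM conv against a literal sliding dot product
        cfg = CNNConfig(n_filters=2, kernel=(3, 3), seed=0)
        model = build_model(cfg, 8, 9, 1, dtype=np.float64)
        X = rng.standard_normal((1, 1, 8, 9))
        out = model._conv(X)
        for f in range(2):
            for i in range(6):
                for j in range(7):
                    direct = np.sum(X[0, 0, i:i+3, j:j+3] * model.W[f]) \
                        + model.b[f]
                    assert out[0, 0, f, i, j] == pytest.approx(direct)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        cfg = CNNConfig(n_filters=3, kernel=(4, 4), n_classes=4, seed=1)
        model = ConvNet(cfg, 12, 16, 2, dtype=np.float64)
        X = rng.standard_normal((5, 2, 12, 16))
        y = rng.integers(0, 4, 5)
        _, grads = model.loss_and_grads(X, y)
        h = 1e-6
        checks = [("W", (0, 1, 2)), ("W", (2, 3, 0)), ("b", (1,)),
                  ("W2", (10, 0)), ("W2", (50, 3)), ("b2", (2,))]
        for name, idx in checks:
            p = getattr(model, name)
            old = p[idx]
            p[idx] = old + h
            up, _ = model.loss_and_grads(X, y)
            p[idx] = old - h
            dn, _ = model.loss_and_grads(X, y)
            p[idx] = old
            numeric = (up - dn) / (2 * h)
            assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestSplits:
    def test_quarter_heldout_matches_published_count(self):
        labels = ["Bul"] * 508 + ["NoBul"] * 508
        plan = make_splits(labels, seed=0)
        assert len(plan.test_idx) == 254
        assert len(plan.train_idx) == 762
        assert len(plan.folds) == 10

    def test_stratified_within_one_trial(self):
        labels = ["A"] * 60 + ["B"] * 61
        plan = make_splits(labels, seed=3)
        y = np.array(labels)
        for cls in ("A", "B"):
            n_total = int(np.sum(y == cls))
            n_test = int(np.sum(y[plan.test_idx] == cls))
            assert abs(n_test - 0.25 * n_total) <= 1

    def test_reproducible_and_disjoint(self):
        labels = ["A", "B"] * 40
        a = make_splits(labels, seed=7)
        b = make_splits(labels, seed=7)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        for (tr1, va1), (tr2, va2) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(va1, va2)
        assert not set(a.test_idx) & set(a.train_idx)
        union = set()
        for tr, va in a.folds:
            assert not set(tr) & set(va)
            assert not set(va) & set(a.test_idx)
            union |= set(va)
        assert union == set(a.train_idx)  # folds partition the training part

    def test_too_small_class_rejected(self):
        with pytest.raises(CNNError):
            make_splits(["A"] * 70 + ["B"] * 8, seed=0)
        with pytest.raises(CNNError):
            make_splits(["A"] * 20, seed=0)


def _separable_data(rng, n=60, planes=2, ch=24, ts=32):
    """Tiny synthetic task: class 1 has a bright patch in fixed rows."""
    X = rng.standard_normal((n, planes, ch, ts)).astype(np.float32) * 0.3
    y = rng.integers(0, 2, n)
    X[y == 1, :, 8:14, :] += 1.5
    return X, y


class TestTraining:
    def test_loss_decreases_and_learns_separable_task(self, rng):
        X, y = _separable_data(rng)
        cfg = CNNConfig(n_classes=2, epochs=4, batch_size=8, seed=2)
        plan = make_splits(["c%d" % v for v in y], seed=0, n_folds=2)
        model, folds, history = train(cfg, plan, X, y, cross_validate=True)
        losses = [h["train_loss"] for h in history]
        assert losses[-1] < losses[0]
        acc = np.mean(model.predict(X[plan.test_idx]) == y[plan.test_idx])
        assert acc >= 0.8
        assert len(folds) == 2

    def test_same_seed_gives_identical_weights_and_metrics(self, rng):
        X, y = _separable_data(rng, n=40)
        cfg = CNNConfig(n_classes=2, epochs=2, batch_size=8, seed=5)
        plan = make_splits(["c%d" % v for v in y], seed=1, n_folds=2)
        m1, f1, h1 = train(cfg, plan, X, y, cross_validate=False)
        m2, f2, h2 = train(cfg, plan, X, y, cross_validate=False)
        for k in ("W", "b", "W2", "b2"):
            np.testing.assert_array_equal(getattr(m1, k), getattr(m2, k))
        assert h1 == h2
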