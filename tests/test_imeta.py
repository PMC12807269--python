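import numpy as np
import pytest

from otuspace import synthdata
from otuspace.imeta import (ImetaConfig, ImetaModel, forward, forward_batch,
                            importance_scores, load_model, log_scale_abundance,
                            loss_and_grads, save_model, taxo_embed,
                            train_end_to_end, train_imeta, upsample_minority)


def tiny_model(k=4, d=3, n_kernels=2, seed=0, **kw):
    rng = np.random.default_rng(seed)
    cfg = ImetaConfig(k=k, d=d, n_kernels=n_kernels, **kw)
    E = rng.normal(size=(k, d))
    A = rng.normal(size=(k, n_kernels))
    w = rng.normal(size=cfg.dense_in)
    return ImetaModel(E, A, w, float(rng.normal()), cfg)


class TestLogScale:
    def test_all_zero_row(self):
        np.testing.assert_array_equal(log_scale_abundance(np.zeros(5)), np.zeros(5))

    def test_floor_maps_to_zero(self):
        x = log_scale_abundance(np.array([1e-5]), r_floor=1e-5)
        assert x[0] == pytest.approx(0.0)

    def test_hundredfold_floor_maps_to_two(self):
        x = log_scale_abundance(np.array([1e-3]), r_floor=1e-5)
        assert x[0] == pytest.approx(2.0)

    def test_raw_mode(self):
        x = log_scale_abundance(np.array([1e-3, 0.0]), mode="raw")
        assert x.tolist() == [-3.0, 0.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_scale_abundance(np.array([-0.1]))


class TestTaxoEmbed:
    def test_hand_example(self):
        M = taxo_embed(np.array([1.0, 2.0]), np.eye(2))
        np.testing.assert_array_equal(M, [[1.0, 0.0], [0.0, 2.0]])

    def test_zero_and_linearity(self):
        E = np.random.default_rng(0).normal(size=(3, 4))
        assert not taxo_embed(np.zeros(3), E).any()
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(taxo_embed(5 * x, E), 5 * taxo_embed(x, E))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="abundance length"):
            taxo_embed(np.zeros(2), np.zeros((3, 4)))


class TestForward:
    def test_zero_input_gives_sigmoid_bias(self):
        m = tiny_model()
        expected = 1 / (1 + np.exp(-m.b))
        assert forward(m, np.zeros(4)) == pytest.approx(expected)

    def test_dense_input_width_contract(self):
        # flatten = n_kernels * d; the sample vector adds d more
        cfg = ImetaConfig(k=10, d=128, n_kernels=3)
        assert cfg.dense_in == 3 * 128
        cfg_s = ImetaConfig(k=10, d=128, n_kernels=3, use_sample_vector=True)
        assert cfg_s.dense_in == 3 * 128 + 128

    def test_scalar_toy_oracle(self):
        # A=2, x=3, E=0.5, dense weight 1, bias 0 -> sigmoid(3)
        cfg = ImetaConfig(k=1, d=1, n_kernels=1)
        m = ImetaModel(np.array([[0.5]]), np.array([[2.0]]), np.array([1.0]), 0.0, cfg)
        assert forward(m, np.array([3.0])) == pytest.approx(1 / (1 + np.exp(-3.0)))

    def test_missing_sample_vector_errors(self):
        m = tiny_model(use_sample_vector=True)
        with pytest.raises(ValueError, match="sample vectors required"):
            forward(m, np.zeros(4))

    def test_sample_vector_enters_dense_layer(self):
        m = tiny_model(use_sample_vector=True, d=3)
        p0 = forward(m, np.zeros(4), np.zeros(3))
        p1 = forward(m, np.zeros(4), np.ones(3))
        assert p0 != p1


class TestGradients:
    @pytest.mark.parametrize("trainable_embedding", [False, True])
    def test_analytic_matches_finite_differences(self, trainable_embedding):
        rng = np.random.default_rng(4)
        m = tiny_model(k=5, d=3, n_kernels=2, seed=4)
        X = rng.normal(size=(7, 5))
        y = rng.integers(0, 2, size=7).astype(float)
        _, grads = loss_and_grads(m, X, None, y, trainable_embedding)

        def loss_of(model):
            return loss_and_grads(model, X, None, y)[0]

        h = 1e-6
        for pname in grads:
            target = {"A": m.A, "w": m.w, "E": m.E}.get(pname)
            if pname == "b":
                m2 = ImetaModel(m.E, m.A, m.w, m.b + h, m.config)
                num = (loss_of(m2) - loss_of(m)) / h
                assert grads["b"][0] == pytest.approx(num, abs=1e-5)
                continue
            flat = target.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                bumped = flat.copy()
                bumped[idx] += h
                kwargs = {"E": m.E, "A": m.A, "w": m.w}
                kwargs[pname] = bumped.reshape(target.shape)
                m2 = ImetaModel(kwargs["E"], kwargs["A"], kwargs["w"], m.b, m.config)
                num = (loss_of(m2) - loss_of(m)) / h
                assert grads[pname].ravel()[idx] == pytest.approx(num, abs=1e-5)


class TestTraining:
    @staticmethod
    def small_task(seed=0):
        return synthdata.classification_task(
            n_samples=120, n_otus=40, n_informative=3, d=8, seed=seed
        )

    def test_upsampling_balances_classes(self):
        y = np.array([1] * 10 + [0] * 90)
        idx = upsample_minority(y, np.random.default_rng(0))
        assert (y[idx] == 1).sum() == 90
        assert (y[idx] == 0).sum() == 90

    def test_single_class_rejected(self):
        X, E, _, _ = self.small_task()
        cfg = ImetaConfig(k=40, d=8)
        with pytest.raises(ValueError, match="both binary classes"):
            train_imeta(X, None, np.zeros(len(X)), E, cfg)

    def test_embedding_frozen_bit_identical(self):
        X, E, y, _ = self.small_task()
        E0 = E.copy()
        cfg = ImetaConfig(k=40, d=8, epochs=3, seed=1)
        model = train_imeta(X, None, y, E, cfg)
        assert np.array_equal(model.E, E0)

    def test_training_deterministic(self):
        X, E, y, _ = self.small_task()
        cfg = ImetaConfig(k=40, d=8, epochs=3, seed=5)
        m1 = train_imeta(X, None, y, E, cfg)
        m2 = train_imeta(X, None, y, E, cfg)
        assert np.array_equal(m1.A, m2.A) and np.array_equal(m1.w, m2.w)

    def test_full_batch_gd_loss_nonincreasing(self):
        X, E, y, _ = self.small_task()
        cfg = ImetaConfig(k=40, d=8, epochs=30, lr=0.05, optimizer="gd",
                          batch_size=None, upsample=False, early_stopping=False)
        model = train_imeta(X, None, y, E, cfg)
        losses = model.history["loss"]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_separable_task_high_f1(self):
        X, E, y, _ = synthdata.classification_task(seed=2)
        n = len(y)
        tr = np.arange(n) < int(0.8 * n)
        cfg = ImetaConfig(k=X.shape[1], d=E.shape[1], seed=2)
        model = train_imeta(X[tr], None, y[tr], E, cfg)
        pred = (forward_batch(model, X[~tr]) >= 0.5).astype(int)
        yt = y[~tr]
        f1 = 2 * ((yt == 1) & (pred == 1)).sum() / (
            2 * ((yt == 1) & (pred == 1)).sum()
            + ((yt == 0) & (pred == 1)).sum()
            + ((yt == 1) & (pred == 0)).sum()
        )
        assert f1 > 0.9


class TestEndToEnd:
    def test_parameter_count_exceeds_by_k_times_d(self):
        X, E, y, _ = TestTraining.small_task()
        cfg = ImetaConfig(k=40, d=8, epochs=1)
        frozen = train_imeta(X, None, y, E, cfg)
        e2e = train_end_to_end(X, None, y, cfg)
        assert e2e.n_trainable() - frozen.n_trainable() == 40 * 8

    def test_embedding_actually_trains(self):
        X, E, y, _ = TestTraining.small_task()
        cfg = ImetaConfig(k=40, d=8, epochs=3, seed=0)
        e2e = train_end_to_end(X, None, y, cfg, E_init=E)
        assert not np.array_equal(e2e.E, E)

    def test_same_weights_same_forward_regardless_of_mode(self):
        m = tiny_model(seed=9)
        twin = ImetaModel(m.E, m.A, m.w, m.b, m.config, trainable_embedding=True)
        x = np.random.default_rng(1).normal(size=4)
        assert forward(m, x) == forward(twin, x)


class TestImportance:
    def test_identical_kernels(self):
        cfg = ImetaConfig(k=3, d=2, n_kernels=3)
        a = np.array([0.5, -2.0, 0.1])
        m = ImetaModel(np.zeros((3, 2)), np.tile(a[:, None], 3),
                       np.zeros(cfg.dense_in), 0.0, cfg)
        rep = importance_scores(m)
        np.testing.assert_allclose(rep["importance"].to_numpy(), np.abs(a))
        assert rep["rank"].tolist() == [2, 1, 3]

    def test_signed_mean_cancellation(self):
        cfg = ImetaConfig(k=1, d=2, n_kernels=3)
        m = ImetaModel(np.zeros((1, 2)), np.array([[1.0, -1.0, 0.0]]),
                       np.zeros(cfg.dense_in), 0.0, cfg)
        rep = importance_scores(m, mode="signed_mean")
        assert rep["signed_mean"].iloc[0] == pytest.approx(0.0)
        assert rep["importance"].iloc[0] == pytest.approx(0.0)
        # the identifiable default does not cancel
        assert importance_scores(m)["importance"].iloc[0] == pytest.approx(2 / 3)

    def test_threshold_flag(self):
        cfg = ImetaConfig(k=2, d=1, n_kernels=1)
        m = ImetaModel(np.zeros((2, 1)), np.array([[0.5], [0.1]]),
                       np.zeros(1), 0.0, cfg)
        rep = importance_scores(m, threshold=0.3)
        assert rep["flagged"].tolist() == [True, False]


def test_checkpoint_roundtrip(tmp_path):
    m = tiny_model(seed=2)
    path = tmp_path / "model.npz"
    save_model(m, path)
    back = load_model(path)
    x = np.random.default_rng(0).normal(size=4)
    assert forward(back, x) == pytest.approx(forward(m, x))
    assert back.config == m.config
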