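import numpy as np
import pytest

from guidegp import simulate_dataset
from guidegp.autodiff import Tensor
from guidegp.model import (
    CapsuleGPNetwork,
    GPHeadConfig,
    HOMConfig,
    PreprocessorConfig,
    TrainConfig,
    TrainedModel,
    combined_loss,
    elbo_loss,
    gp_predict,
    lr_at_epoch,
    train_model,
)
from guidegp.nn import HOMEncoder
from guidegp.sequence_io import LabeledDataset, ActivityScale, encode_batch

from conftest import SMALL_LENGTH, small_configs


def make_net(kind="conv1d", shape=(4, 10), seed=0, **kw):
    pcfg = PreprocessorConfig(kind=kind, channels=kw.pop("channels", 8),
                              hidden_size=8, kernel_width=kw.pop("kernel_width", 3))
    return CapsuleGPNetwork(shape, pcfg, HOMConfig(n_capsules=3, capsule_dim=4),
                            GPHeadConfig(n_features=32), np.random.default_rng(seed))


class TestPreprocessing:
    def test_conv1d_output_shape(self):
        net = make_net(channels=32, kernel_width=5, shape=(4, 23))
        out = net.preprocess(Tensor(np.zeros((7, 4, 23))))
        assert out.shape == (7, 32, 23)

    def test_recurrent_output_shape(self):
        net = make_net(kind="recurrent", shape=(4, 10))
        out = net.preprocess(Tensor(np.zeros((3, 4, 10))))
        assert out.shape == (3, 8, 10)

    def test_conv2d_pair_output_shape(self):
        net = make_net(kind="conv2d", shape=(2, 4, 10))
        out = net.preprocess(Tensor(np.zeros((3, 2, 4, 10))))
        assert out.shape == (3, 8, 4, 10)

    def test_conv2d_rejected_for_single_guides(self):
        with pytest.raises(ValueError, match="pair"):
            make_net(kind="conv2d", shape=(4, 10))

    def test_recurrent_rejected_for_pairs(self):
        with pytest.raises(ValueError, match="single-guide"):
            make_net(kind="recurrent", shape=(2, 4, 10))

    def test_zero_weights_give_zero_features(self, rng):
        net = make_net()
        net.pre.W.data[:] = 0.0
        net.pre.b.data[:] = 0.0
        out = net.preprocess(Tensor(rng.random((5, 4, 10))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_deterministic_at_fixed_weights(self, rng):
        net = make_net()
        x = rng.random((5, 4, 10))
        a = net.preprocess(Tensor(x)).data
        b = net.preprocess(Tensor(x)).data
        np.testing.assert_array_equal(a, b)


class TestHOMEncoder:
    def test_outputs_strictly_inside_bounds_on_random_stress(self, rng):
        enc = HOMEncoder(6, n_capsules=5, capsule_dim=4, rng=rng)
        x = Tensor(100.0 * rng.standard_normal((10000, 6)))
        out = enc(x).data
        assert out.shape == (10000, 5, 4)
        assert np.all(out > -0.5) and np.all(out < 0.5)

    def test_center_hit_gives_zero(self, rng):
        enc = HOMEncoder(6, n_capsules=2, capsule_dim=3, rng=rng)
        # zero input through affine(b=0) and batchnorm stays zero -> sigmoid 0.5
        for i in range(2):
            getattr(enc, f"linear{i}").b.data[:] = 0.0
        out = enc(Tensor(np.zeros((4, 6)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_saturated_preactivation_approaches_half(self, rng):
        enc = HOMEncoder(2, n_capsules=1, capsule_dim=2, rng=rng)
        enc.eval()
        enc.bn0.running_mean[:] = 0.0
        enc.bn0.running_var[:] = 1.0
        enc.linear0.W.data[:] = 15.0
        out = enc(Tensor(np.ones((1, 2)))).data
        assert np.all(out > -0.5)
        np.testing.assert_allclose(out, -0.5, atol=1e-6)


class TestLosses:
    def setup_method(self):
        self.net = make_net(shape=(4, SMALL_LENGTH))
        self.net.n_train = 32
        rng = np.random.default_rng(5)
        data, _ = simulate_dataset(32, SMALL_LENGTH, seed=3)
        self.batch = (data.inputs, data.labels)

    def test_losses_are_finite_scalars(self):
        loss, yhat = elbo_loss(self.net, self.batch, rng=np.random.default_rng(0))
        assert np.isfinite(loss.data) and loss.data.shape == ()

    def test_combined_equals_elbo_plus_half_mse(self):
        X, y = self.batch
        l1, yhat1 = elbo_loss(self.net, self.batch, rng=np.random.default_rng(7))
        l2, yhat2 = combined_loss(self.net, self.batch, rng=np.random.default_rng(7),
                                  alpha=0.5)
        mse = float(((y[:, None] - yhat1.data) ** 2).mean())
        np.testing.assert_allclose(float(l2.data), float(l1.data) + 0.5 * mse,
                                   rtol=1e-10)
        assert float(l2.data) >= float(l1.data)  # equality iff MSE = 0

    def test_mse_term_scales_quadratically(self):
        X, y = self.batch
        l0, yhat = elbo_loss(self.net, self.batch, rng=np.random.default_rng(7))
        resid = y[:, None] - yhat.data
        # shifting labels to double the residuals quadruples the MSE part
        y2 = yhat.data[:, 0] + 2 * resid[:, 0]
        l2, yhat2 = combined_loss(self.net, (X, y2), rng=np.random.default_rng(7))
        mse1 = float((resid**2).mean())
        np.testing.assert_allclose(float(l2.data) - float(
            elbo_loss(self.net, (X, y2), rng=np.random.default_rng(7))[0].data),
            0.5 * 4 * mse1, rtol=1e-8)

    def test_kl_zero_when_variational_equals_prior(self):
        self.net.gp1.q_mu.data[:] = 0.0
        self.net.gp1.q_log_sigma.data[:] = 0.0
        assert float(self.net.gp1.kl().data) == pytest.approx(0.0, abs=1e-12)


class TestTraining:
    def test_lr_schedule_values(self):
        assert lr_at_epoch(0) == pytest.approx(0.01)
        assert lr_at_epoch(10) == pytest.approx(0.009)
        assert lr_at_epoch(59) == pytest.approx(0.01 * 0.9**5)

    def test_empty_dataset_raises(self):
        ds = LabeledDataset(np.zeros((0, 4, 8)), np.zeros(0), ActivityScale(0, 1))
        with pytest.raises(ValueError, match="empty"):
            train_model(ds)

    def test_unscaled_labels_rejected(self):
        data, _ = simulate_dataset(20, SMALL_LENGTH, seed=0)
        bad = LabeledDataset(data.inputs, data.labels * 3.0, data.scale)
        with pytest.raises(ValueError, match="rescaled"):
            train_model(bad, *small_configs())

    def test_loss_decreases_majority_of_seeds(self):
        wins = 0
        for seed in range(3):
            data, _ = simulate_dataset(200, SMALL_LENGTH, seed=seed)
            model = train_model(data, *small_configs(epochs=5, seed=seed))
            wins += model.training_log[-1] < model.training_log[0]
        assert wins >= 2

    def test_same_seed_identical_parameters(self):
        data, _ = simulate_dataset(60, SMALL_LENGTH, seed=1)
        cfgs = small_configs(epochs=2, seed=9)
        m1 = train_model(data, *cfgs)
        m2 = train_model(data, *cfgs)
        for (k1, p1), (k2, p2) in zip(m1.net.named_parameters(),
                                      m2.net.named_parameters()):
            assert k1 == k2
            np.testing.assert_allclose(p1.data, p2.data, atol=1e-6)


class TestPrediction:
    def test_std_strictly_positive(self, small_model, small_dataset):
        data, _ = small_dataset
        pred = small_model.predict(data.inputs[:20], seed=0)
        assert np.all(pred.std > 0)

    def test_fewer_than_two_samples_rejected(self, small_model, small_dataset):
        data, _ = small_dataset
        with pytest.raises(ValueError, match="at least 2"):
            gp_predict(small_model, data.inputs[:2], n_samples=1)

    def test_mean_and_std_are_sample_statistics(self, small_model, small_dataset):
        data, _ = small_dataset
        pred = small_model.predict(data.inputs[:5], n_samples=16, seed=1)
        np.testing.assert_allclose(pred.mean, pred.samples.mean(axis=1))
        np.testing.assert_allclose(pred.std, pred.samples.std(axis=1, ddof=1))

    def test_mean_stable_across_resampling(self, small_model, small_dataset):
        data, _ = small_dataset
        S = 4096
        p1 = small_model.predict(data.inputs[:10], n_samples=S, seed=1)
        p2 = small_model.predict(data.inputs[:10], n_samples=S, seed=2)
        tol = 3 * np.maximum(p1.std, p2.std) / np.sqrt(S)
        assert np.all(np.abs(p1.mean - p2.mean) < 2 * tol)

    def test_constant_labels_recovered(self):
        data, _ = simulate_dataset(150, SMALL_LENGTH, seed=4)
        ds = LabeledDataset(data.inputs, np.full(len(data), 0.5),
                            ActivityScale(0, 1))
        model = train_model(ds, *small_configs(epochs=20, seed=0))
        pred = model.predict(data.inputs[:50], seed=0)
        assert np.abs(pred.mean - 0.5).mean() < 0.05


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, small_model, small_dataset,
                                              tmp_path):
        data, _ = small_dataset
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = TrainedModel.load(path)
        p1 = small_model.predict(data.inputs[:8], seed=3)
        p2 = loaded.predict(data.inputs[:8], seed=3)
        np.testing.assert_allclose(p1.mean, p2.mean)
        np.testing.assert_allclose(p1.std, p2.std)
        assert loaded.scale == small_model.scale

    def test_predict_accepts_sequences(self, small_model):
        pred = small_model.predict(["ACGTACGTACGT", "TTTTTTTTTTTT"], seed=0)
        assert pred.mean.shape == (2,)
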