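"""Deep-kernel model for cleavage-efficiency regression with uncertainty.

The network is a pipeline of three parts:

1. a preprocessing subnetwork — a coordinate-augmented 1D/2D convolution with
   leaky-ReLU activation, or a stack of four LSTM layers — extracting k-mer
   level features from one-hot sequences;
2. a Hit-or-Miss capsule encoder mapping those features to bounded "guide
   space" coordinates in (-0.5, 0.5);
3. a two-layer variational Gaussian-process head (first layer: 2 outputs,
   linear mean; second layer: 1 output, constant mean) with a Gaussian
   likelihood, trained by maximizing the evidence lower bound (ELBO),
   optionally plus a mean-squared-error term weighted by alpha.

Training uses Adam with learning rate 0.01 multiplied by 0.9 every ten
epochs, 60 epochs by default; the expected log-likelihood term is computed
in closed form for the output layer (doubly stochastic variational
inference: the inner layer is resolved by reparameterized marginal
sampling).  Predictions are obtained by drawing samples through both GP
layers and the likelihood; the reported mean and standard deviation are the
sample mean and sample standard deviation (ddof=1), so the predictive
spread includes observation noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import (
    Adam,
    BatchNorm1d,
    CoordConv1d,
    CoordConv2d,
    GaussianLikelihood,
    HOMEncoder,
    LSTMStack,
    Module,
    RFFGPLayer,
)
from .sequence_io import ActivityScale, LabeledDataset, encode_batch, encode_pair_batch

__all__ = [
    "PreprocessorConfig",
    "HOMConfig",
    "GPHeadConfig",
    "TrainConfig",
    "PosteriorPrediction",
    "CapsuleGPNetwork",
    "TrainedModel",
    "elbo_loss",
    "combined_loss",
    "train_model",
    "gp_predict",
    "lr_at_epoch",
]

CHECKPOINT_VERSION = 1


@dataclass
class PreprocessorConfig:
    kind: str = "conv1d"  # conv1d | conv2d | recurrent
    channels: int = 4
    hidden_size: int = 32
    kernel_width: int = 5
    kernel_height: int = 3  # conv2d only
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.kind not in ("conv1d", "conv2d", "recurrent"):
            raise ValueError(f"unknown preprocessor kind: {self.kind!r}")


@dataclass
class HOMConfig:
    n_capsules: int = 5
    capsule_dim: int = 4


@dataclass
class GPHeadConfig:
    latent_dim: int = 2          # output dim of the first GP layer
    n_features: int = 128        # random Fourier features per layer
    init_noise_var: float = 0.01


@dataclass
class TrainConfig:
    loss: str = "elbo"           # elbo | elbo_mse
    alpha: float = 0.5           # weight of the MSE term for elbo_mse
    lr0: float = 0.01
    decay: float = 0.9
    decay_every: int = 10
    epochs: int = 60
    batch_size: int = 128
    seed: int = 0
    n_train_samples: int = 4     # MC samples for the expected log-likelihood
    n_posterior_samples: int = 64
    weight_decay: float = 0.2    # decoupled L2 on the encoder weights

    def __post_init__(self):
        if self.loss not in ("elbo", "elbo_mse"):
            raise ValueError(f"unknown loss: {self.loss!r}")


@dataclass
class PosteriorPrediction:
    """Batched predictive summary: arrays of shape (n,), (n,), (n, S)."""

    mean: np.ndarray
    std: np.ndarray
    samples: np.ndarray


def lr_at_epoch(epoch: int, lr0: float = 0.01, decay: float = 0.9,
                every: int = 10) -> float:
    """Step-wise schedule: lr0 * decay ** floor(epoch / every)."""
    return lr0 * decay ** (epoch // every)


class CapsuleGPNetwork(Module):
    """Preprocessor + HOM capsules + two stacked variational GP layers."""

    def __init__(self, input_shape: tuple, pcfg: PreprocessorConfig,
                 hcfg: HOMConfig, gcfg: GPHeadConfig, rng: np.random.Generator):
        super().__init__()
        self.input_shape = tuple(input_shape)
        self.pcfg, self.hcfg, self.gcfg = pcfg, hcfg, gcfg
        pair = len(input_shape) == 3
        if pair and input_shape[0] != 2 or not pair and input_shape[0] != 4:
            raise ValueError(f"unsupported input shape {input_shape}")
        n = input_shape[-1]
        if pcfg.kind == "conv2d":
            if not pair:
                raise ValueError("conv2d preprocessing requires pair inputs (2, 4, N)")
            self.pre = CoordConv2d(2, pcfg.channels,
                                   (pcfg.kernel_height, pcfg.kernel_width), rng)
            feat_dim = pcfg.channels * 4 * n
        elif pcfg.kind == "recurrent":
            if pair:
                raise ValueError("recurrent preprocessing supports single-guide inputs only")
            self.pre = LSTMStack(4, pcfg.hidden_size, 4, rng)
            feat_dim = pcfg.hidden_size * n
        else:
            if pair:
                raise ValueError("conv1d preprocessing requires single-guide inputs (4, N)")
            self.pre = CoordConv1d(4, pcfg.channels, pcfg.kernel_width, rng)
            feat_dim = pcfg.channels * n
        self.hom = HOMEncoder(feat_dim, hcfg.n_capsules, hcfg.capsule_dim, rng)
        coord_dim = hcfg.n_capsules * hcfg.capsule_dim
        self.gp1 = RFFGPLayer(coord_dim, gcfg.latent_dim, gcfg.n_features,
                              mean="linear", rng=rng)
        self.gp2 = RFFGPLayer(gcfg.latent_dim, 1, gcfg.n_features,
                              mean="constant", rng=rng)
        self.likelihood = GaussianLikelihood(gcfg.init_noise_var)
        self.n_train = None  # set by train_model; scales the KL term

    # -- differentiable paths --------------------------------------------
    def preprocess(self, x: Tensor) -> Tensor:
        feats = self.pre(x)
        if self.pcfg.kind != "recurrent":
            feats = feats.leaky_relu(self.pcfg.leaky_slope)
        return feats

    def encode(self, x: Tensor) -> Tensor:
        """One-hot batch -> guide-space coordinates (B, n_capsules, capsule_dim)."""
        feats = self.preprocess(x)
        flat = feats.reshape(feats.shape[0], -1)
        return self.hom(flat)

    def coords_flat(self, x: Tensor) -> Tensor:
        c = self.encode(x)
        return c.reshape(c.shape[0], -1)

    def sample_output(self, coords: Tensor, rng: np.random.Generator) -> Tensor:
        """One pathwise sample of the latent function f(x), shape (B, 1)."""
        f1 = self.gp1.sample(coords, rng)
        return self.gp2.sample(f1, rng)

    def output_moments(self, coords: Tensor,
                       rng: np.random.Generator) -> tuple[Tensor, Tensor]:
        """Marginal mean/variance of f2 given one sampled first-layer draw.

        The first layer is resolved by per-point marginal sampling (mu1 +
        sqrt(var1) * eps, reparameterized); the second layer's moments are
        then exact, so the expected log-likelihood needs no MC over q(w2).
        """
        mu1, var1 = self.gp1.moments(coords)
        eps = rng.standard_normal(mu1.shape)
        f1 = mu1 + (var1 + 1e-12) ** 0.5 * eps
        return self.gp2.moments(f1)

    def kl(self) -> Tensor:
        return self.gp1.kl() + self.gp2.kl()

    # -- fast numpy evaluation path (no gradients) ------------------------
    @staticmethod
    def _gp_moments_np(layer: RFFGPLayer, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ls = np.exp(layer.log_lengthscale.data)
        z = x @ (layer.omega.T / ls[:, None])
        amp = np.exp(2.0 * layer.log_outputscale.data) * (2.0 / layer.n_features)
        phi = np.sqrt(amp) * np.concatenate([np.cos(z), np.sin(z)], axis=1)
        if layer.mean_kind == "linear":
            m = x @ layer.mean_fn.W.data + layer.mean_fn.b.data
        else:
            m = layer.mean_const.data[None, :]
        mu = m + phi @ layer.q_mu.data
        var = phi**2 @ np.exp(2.0 * layer.q_log_sigma.data)
        return mu, var


def elbo_loss(net: CapsuleGPNetwork, batch: tuple[np.ndarray, np.ndarray],
              rng: np.random.Generator | None = None,
              n_samples: int | None = None) -> tuple[Tensor, Tensor]:
    """Per-datapoint negative ELBO (the minimized objective).

    The expected log-likelihood uses the closed-form Gaussian expectation of
    the output layer, averaged over reparameterized samples of the first
    layer.  Returns (loss, yhat) where yhat is the mean of the sampled
    predictive means — the quantity the MSE term of the combined loss
    compares to y.
    """
    X, y = batch
    rng = rng if rng is not None else np.random.default_rng(0)
    n_samples = n_samples or 4
    B = len(y)
    n_total = net.n_train or B
    coords = net.coords_flat(Tensor(np.asarray(X, dtype=float)))
    y_col = np.asarray(y, dtype=float)[:, None]
    ll_sum = None
    f_sum = None
    for _ in range(n_samples):
        mu2, var2 = net.output_moments(coords, rng)
        ll = net.likelihood.expected_log_prob(y_col, mu2, var2)
        ll_sum = ll if ll_sum is None else ll_sum + ll
        f_sum = mu2 if f_sum is None else f_sum + mu2
    e_term = ll_sum / float(n_samples * B)
    kl = net.kl() / float(n_total)
    yhat = f_sum / float(n_samples)
    loss = -(e_term - kl)
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite ELBO loss; aborting")
    return loss, yhat


def combined_loss(net: CapsuleGPNetwork, batch: tuple[np.ndarray, np.ndarray],
                  rng: np.random.Generator | None = None,
                  alpha: float = 0.5,
                  n_samples: int | None = None) -> tuple[Tensor, Tensor]:
    """Negative ELBO plus alpha * MSE(y, yhat), yhat = mean predictive sample."""
    X, y = batch
    loss, yhat = elbo_loss(net, batch, rng=rng, n_samples=n_samples)
    resid = Tensor(np.asarray(y, dtype=float)[:, None]) - yhat
    mse = (resid**2).mean()
    total = loss + alpha * mse
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite combined loss; aborting")
    return total, yhat


@dataclass
class TrainedModel:
    """A trained network bundled with its label scale and provenance."""

    net: CapsuleGPNetwork
    scale: ActivityScale
    pcfg: PreprocessorConfig
    hcfg: HOMConfig
    gcfg: GPHeadConfig
    tcfg: TrainConfig
    training_log: list[float] = field(default_factory=list)

    @property
    def input_length(self) -> int:
        return self.net.input_shape[-1]

    @property
    def is_pair(self) -> bool:
        return len(self.net.input_shape) == 3

    def _as_inputs(self, X) -> np.ndarray:
        if isinstance(X, LabeledDataset):
            return X.inputs
        X = np.asarray(X) if not isinstance(X, list) else X
        if isinstance(X, list):
            if self.is_pair:
                return encode_pair_batch(X)
            return encode_batch(X)
        if X.ndim == len(self.net.input_shape):
            return X[None]
        return X

    def encode(self, X) -> np.ndarray:
        """Guide-space coordinates, (n, n_capsules, capsule_dim), eval mode."""
        self.net.eval()
        return self.net.encode(Tensor(self._as_inputs(X).astype(float))).data

    def predict(self, X, n_samples: int | None = None,
                seed: int = 0) -> PosteriorPrediction:
        return gp_predict(self, X, n_samples or self.tcfg.n_posterior_samples, seed)

    def predict_meanvar(self, X, n_samples: int | None = None,
                        seed: int = 0) -> np.ndarray:
        """(n, 2) array of [predictive mean, predictive variance]."""
        p = self.predict(X, n_samples=n_samples, seed=seed)
        return np.column_stack([p.mean, p.std**2])

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        cfg = {
            "version": CHECKPOINT_VERSION,
            "input_shape": list(self.net.input_shape),
            "pcfg": dataclasses.asdict(self.pcfg),
            "hcfg": dataclasses.asdict(self.hcfg),
            "gcfg": dataclasses.asdict(self.gcfg),
            "tcfg": dataclasses.asdict(self.tcfg),
            "scale": dataclasses.asdict(self.scale),
            "training_log": self.training_log,
        }
        state = {f"param::{k}": v for k, v in self.net.state_arrays().items()}
        np.savez(path, config=json.dumps(cfg), **state)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        archive = np.load(path, allow_pickle=False)
        cfg = json.loads(str(archive["config"]))
        if cfg["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {cfg['version']}")
        pcfg = PreprocessorConfig(**cfg["pcfg"])
        hcfg = HOMConfig(**cfg["hcfg"])
        gcfg = GPHeadConfig(**cfg["gcfg"])
        tcfg = TrainConfig(**cfg["tcfg"])
        net = CapsuleGPNetwork(tuple(cfg["input_shape"]), pcfg, hcfg, gcfg,
                               np.random.default_rng(tcfg.seed))
        state = {k[len("param::"):]: archive[k]
                 for k in archive.files if k.startswith("param::")}
        net.load_state_arrays(state)
        net.eval()
        return cls(net, ActivityScale(**cfg["scale"]), pcfg, hcfg, gcfg, tcfg,
                   training_log=list(cfg["training_log"]))


def train_model(
    data: LabeledDataset,
    pcfg: PreprocessorConfig | None = None,
    hcfg: HOMConfig | None = None,
    gcfg: GPHeadConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> TrainedModel:
    """Fit the full model on a labeled dataset.

    Deterministic given ``tcfg.seed``: a single generator drives parameter
    init, epoch shuffling and MC sampling.  Raises on an empty dataset or a
    non-finite loss.
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    pcfg = pcfg or PreprocessorConfig(
        kind="conv2d" if data.is_pair else "conv1d"
    )
    hcfg = hcfg or HOMConfig()
    gcfg = gcfg or GPHeadConfig()
    tcfg = tcfg or TrainConfig()
    y = np.asarray(data.labels, dtype=float)
    if y.min() < -1e-9 or y.max() > 1 + 1e-9:
        raise ValueError("labels must be rescaled to [0, 1] before training")
    rng = np.random.default_rng(tcfg.seed)
    net = CapsuleGPNetwork(data.inputs.shape[1:], pcfg, hcfg, gcfg, rng)
    net.n_train = len(data)
    encoder_params = {id(p) for p in net.pre.parameters()}
    encoder_params |= {id(p) for p in net.hom.parameters()}
    params = net.parameters()
    opt = Adam(params, lr=tcfg.lr0, weight_decay=tcfg.weight_decay,
               decay_mask=[id(p) in encoder_params for p in params])
    X = data.inputs.astype(float)
    log: list[float] = []
    loss_fn = combined_loss if tcfg.loss == "elbo_mse" else elbo_loss
    net.train()
    for epoch in range(tcfg.epochs):
        opt.lr = lr_at_epoch(epoch, tcfg.lr0, tcfg.decay, tcfg.decay_every)
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(data), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            if len(idx) < 2:
                continue  # batchnorm needs at least two examples
            net.zero_grad()
            if tcfg.loss == "elbo_mse":
                loss, _ = loss_fn(net, (X[idx], y[idx]), rng=rng,
                                  alpha=tcfg.alpha, n_samples=tcfg.n_train_samples)
            else:
                loss, _ = loss_fn(net, (X[idx], y[idx]), rng=rng,
                                  n_samples=tcfg.n_train_samples)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    net.eval()
    return TrainedModel(net, data.scale, pcfg, hcfg, gcfg, tcfg, training_log=log)


def gp_predict(model: TrainedModel, X, n_samples: int = 64,
               seed: int = 0) -> PosteriorPrediction:
    """Sample the likelihood-inclusive posterior predictive distribution.

    Draws ``n_samples`` marginal samples through both GP layers plus Gaussian
    observation noise; returns per-input mean, standard deviation (ddof=1,
    strictly positive) and the raw samples.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    net = model.net
    net.eval()
    inputs = model._as_inputs(X).astype(float)
    coords = net.coords_flat(Tensor(inputs)).data
    rng = np.random.default_rng(seed)
    noise_sd = float(np.sqrt(net.likelihood.noise_var().data))
    n = len(inputs)
    samples = np.empty((n, n_samples))
    mu1, var1 = net._gp_moments_np(net.gp1, coords)
    for s in range(n_samples):
        f1 = mu1 + np.sqrt(var1) * rng.standard_normal(mu1.shape)
        mu2, var2 = net._gp_moments_np(net.gp2, f1)
        samples[:, s] = (mu2[:, 0]
                         + np.sqrt(var2[:, 0]) * rng.standard_normal(n)
                         + noise_sd * rng.standard_normal(n))
    return PosteriorPrediction(
        mean=samples.mean(axis=1),
        std=samples.std(axis=1, ddof=1),
        samples=samples,
    )
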