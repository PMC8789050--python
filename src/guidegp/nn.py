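"""Network building blocks: coordinate-augmented convolutions, stacked LSTMs,
Hit-or-Miss capsules, random-feature variational GP layers, and Adam.

All layers operate on :class:`~guidegp.autodiff.Tensor` and keep their
parameters as tensors with ``requires_grad=True``.  Randomness is injected
through explicit ``numpy.random.Generator`` objects so training is
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, cat, conv1d, conv2d

__all__ = [
    "Module",
    "Linear",
    "BatchNorm1d",
    "CoordConv1d",
    "CoordConv2d",
    "LSTMStack",
    "HOMEncoder",
    "RFFGPLayer",
    "GaussianLikelihood",
    "Adam",
]


class Module:
    """Base class with parameter bookkeeping and a train/eval switch."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, child in self._children.items():
            out.extend(child.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for c in self._children.values():
            c.train()

    def eval(self) -> None:
        self.training = False
        for c in self._children.values():
            c.eval()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters plus non-trainable buffers, for checkpointing."""
        state = {k: v.data for k, v in self.named_parameters()}
        state.update(self.buffers())
        return state

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k in getattr(self, "_buffer_names", ()):
            out[prefix + k] = getattr(self, k)
        for name, child in self._children.items():
            out.update(child.buffers(prefix + name + "."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data = np.asarray(state[k], dtype=np.float64)
        self._load_buffers(state)

    def _load_buffers(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k in getattr(self, "_buffer_names", ()):
            setattr(self, k, np.asarray(state[prefix + k], dtype=np.float64))
        for name, child in self._children.items():
            child._load_buffers(state, prefix + name + ".")


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(in_dim)
        self.W = self.register("W", rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.b = self.register("b", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm1d(Module):
    """Batch statistics at train time, running statistics at eval time."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps) ** 0.5
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class CoordConv1d(Module):
    """1-D convolution over one-hot sequence augmented with a normalized
    positional coordinate channel, followed by nothing (activation is the
    caller's job)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_width: int,
                 rng: np.random.Generator):
        super().__init__()
        cin = in_channels + 1  # + coordinate channel
        scale = 1.0 / np.sqrt(cin * kernel_width)
        self.W = self.register(
            "W", rng.uniform(-scale, scale, size=(out_channels, cin, kernel_width))
        )
        self.b = self.register("b", np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, N = x.shape
        coord = np.broadcast_to(np.linspace(-1.0, 1.0, N)[None, None, :], (B, 1, N))
        xin = cat([x, Tensor(coord.copy())], axis=1)
        return conv1d(xin, self.W, self.b)


class CoordConv2d(Module):
    """2-D coordinate-augmented convolution for (guide, target) pair images
    of shape (B, 2, 4, N); adds row and column coordinate channels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        cin = in_channels + 2
        kh, kw = kernel_size
        scale = 1.0 / np.sqrt(cin * kh * kw)
        self.W = self.register(
            "W", rng.uniform(-scale, scale, size=(out_channels, cin, kh, kw))
        )
        self.b = self.register("b", np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, N = x.shape
        rows = np.broadcast_to(
            np.linspace(-1.0, 1.0, H)[None, None, :, None], (B, 1, H, N)
        )
        cols = np.broadcast_to(
            np.linspace(-1.0, 1.0, N)[None, None, None, :], (B, 1, H, N)
        )
        xin = cat([x, Tensor(rows.copy()), Tensor(cols.copy())], axis=1)
        return conv2d(xin, self.W, self.b)


class _LSTMLayer(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        scale = 1.0 / np.sqrt(hidden_size)
        self.Wx = self.register(
            "Wx", rng.uniform(-scale, scale, size=(input_size, 4 * hidden_size))
        )
        self.Wh = self.register(
            "Wh", rng.uniform(-scale, scale, size=(hidden_size, 4 * hidden_size))
        )
        self.b = self.register("b", np.zeros(4 * hidden_size))

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        B = xs[0].shape[0]
        H = self.hidden_size
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        out = []
        for x_t in xs:
            gates = x_t @ self.Wx + h @ self.Wh + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out


class LSTMStack(Module):
    """Stacked LSTM layers run along the sequence-position axis.

    Input (B, C, N); output (B, hidden, N) — the per-position hidden state of
    the last layer, so the downstream flattening matches the conv variant.
    """

    def __init__(self, input_size: int, hidden_size: int, n_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_layers = n_layers
        for i in range(n_layers):
            setattr(
                self,
                f"layer{i}",
                _LSTMLayer(input_size if i == 0 else hidden_size, hidden_size, rng),
            )

    def __call__(self, x: Tensor) -> Tensor:
        N = x.shape[2]
        seq = [x[:, :, t] for t in range(N)]
        for i in range(self.n_layers):
            seq = getattr(self, f"layer{i}")(seq)
        cols = [h.reshape(h.shape[0], -1, 1) for h in seq]
        return cat(cols, axis=2)


class HOMEncoder(Module):
    """Hit-or-Miss capsule bank.

    Each capsule maps the flattened feature vector through an affine layer,
    per-capsule batch normalization and a sigmoid, and reports the deviation
    from the fixed center C = 0.5:  O_i(x) = 0.5 - sigmoid(bn_i(linear_i(x))).
    Outputs lie strictly inside (-0.5, 0.5) and are stacked to
    (B, n_capsules, capsule_dim) — the guide's coordinates in guide space.
    """

    CENTER = 0.5

    def __init__(self, in_dim: int, n_capsules: int, capsule_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_capsules = n_capsules
        self.capsule_dim = capsule_dim
        for i in range(n_capsules):
            setattr(self, f"linear{i}", Linear(in_dim, capsule_dim, rng))
            setattr(self, f"bn{i}", BatchNorm1d(capsule_dim))

    def __call__(self, x: Tensor) -> Tensor:
        outs = []
        for i in range(self.n_capsules):
            lin = getattr(self, f"linear{i}")
            bn = getattr(self, f"bn{i}")
            o = self.CENTER - bn(lin(x)).sigmoid()
            outs.append(o.reshape(o.shape[0], 1, self.capsule_dim))
        return cat(outs, axis=1)


class RFFGPLayer(Module):
    """Variational GP layer using a random-feature expansion of an RBF kernel.

    The stationary kernel k(x, x') = s^2 exp(-||(x - x')/l||^2 / 2) is
    represented through random Fourier features phi(x) =
    sqrt(s^2 / R) [cos(Z x), sin(Z x)] with Z drawn once from N(0, diag(1/l^2));
    the GP function is f(x) = m(x) + phi(x)^T w with a Gaussian variational
    posterior q(w) = N(mu, diag(sigma^2)) against the standard-normal prior.
    Lengthscales l, outputscale s, the mean function, and q are all learned.
    KL(q || p) is closed-form; sampling w gives pathwise function samples, so
    layers can be stacked (doubly stochastic variational inference).
    """

    def __init__(self, in_dim: int, out_dim: int, n_features: int,
                 mean: str, rng: np.random.Generator):
        super().__init__()
        if n_features % 2 != 0:
            raise ValueError("n_features must be even (cos/sin pairs)")
        if mean not in ("linear", "constant"):
            raise ValueError(f"unknown mean function: {mean!r}")
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.n_features = n_features
        self.mean_kind = mean
        self.omega = rng.standard_normal((n_features // 2, in_dim))
        self._buffer_names = ("omega",)
        self.log_lengthscale = self.register("log_lengthscale", np.zeros(in_dim))
        self.log_outputscale = self.register("log_outputscale", np.zeros(()))
        self.q_mu = self.register(
            "q_mu", 0.1 * rng.standard_normal((n_features, out_dim))
        )
        self.q_log_sigma = self.register(
            "q_log_sigma", np.full((n_features, out_dim), -2.0)
        )
        if mean == "linear":
            self.mean_fn = Linear(in_dim, out_dim, rng)
        else:
            self.mean_const = self.register("mean_const", np.zeros(out_dim))

    def features(self, x: Tensor) -> Tensor:
        ls = self.log_lengthscale.exp().reshape(-1, 1)  # (in_dim, 1)
        z = x @ (Tensor(self.omega.T) / ls)
        amp = (2.0 * self.log_outputscale).exp() * (2.0 / self.n_features)
        return amp**0.5 * cat([z.cos(), z.sin()], axis=1)

    def mean(self, x: Tensor) -> Tensor:
        if self.mean_kind == "linear":
            return self.mean_fn(x)
        return Tensor(np.zeros((x.shape[0], self.out_dim))) + self.mean_const

    def sample(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        """One pathwise function sample f(x) for the whole batch."""
        eps = rng.standard_normal((self.n_features, self.out_dim))
        w = self.q_mu + self.q_log_sigma.exp() * eps
        return self.mean(x) + self.features(x) @ w

    def moments(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Marginal mean and variance of q(f(x)) per input, both (B, out).

        Exact under q(w) = N(mu, diag(sigma^2)); used for the analytic
        expected log-likelihood and for low-variance marginal sampling.
        """
        phi = self.features(x)
        mu = self.mean(x) + phi @ self.q_mu
        var = (phi * phi) @ (2.0 * self.q_log_sigma).exp()
        return mu, var

    def kl(self) -> Tensor:
        s2 = (2.0 * self.q_log_sigma).exp()
        return 0.5 * (self.q_mu**2 + s2 - 1.0 - 2.0 * self.q_log_sigma).sum()


class GaussianLikelihood(Module):
    """Gaussian observation model with learned noise variance (softplus)."""

    def __init__(self, init_noise_var: float = 0.01, floor: float = 1e-6):
        super().__init__()
        raw = np.log(np.expm1(init_noise_var))
        self.raw_noise = self.register("raw_noise", np.asarray(raw))
        self.floor = floor

    def noise_var(self) -> Tensor:
        return self.raw_noise.softplus() + self.floor

    def log_prob(self, y: np.ndarray, f: Tensor) -> Tensor:
        """Elementwise log N(y | f, noise_var), summed over the batch."""
        var = self.noise_var()
        resid2 = (Tensor(y) - f) ** 2
        n = float(np.asarray(y).size)
        return -0.5 * (resid2 / var).sum() - 0.5 * n * (
            var.log() + float(np.log(2.0 * np.pi))
        )

    def expected_log_prob(self, y: np.ndarray, f_mu: Tensor, f_var: Tensor) -> Tensor:
        """E_{q(f)}[log N(y | f, noise_var)] in closed form, summed over batch.

        Equals log N(y | f_mu, noise_var) - f_var / (2 noise_var); exact for a
        Gaussian q(f), so variational-parameter gradients carry no Monte-Carlo
        noise.
        """
        var = self.noise_var()
        resid2 = (Tensor(y) - f_mu) ** 2
        n = float(np.asarray(y).size)
        return -0.5 * ((resid2 + f_var) / var).sum() - 0.5 * n * (
            var.log() + float(np.log(2.0 * np.pi))
        )


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay.

    ``decay_mask`` selects which parameters are decayed; by convention the
    encoder weights are regularized while GP hyper-/variational parameters
    and the likelihood noise are not.
    """

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_mask: list[bool] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(params)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self.decay_mask[i]:
                p.data = p.data - self.lr * self.weight_decay * p.data
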