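"""Model interpretation: accumulated local effects, sequence logos,
guide-space embedding and clustering.

For one-hot encoded sequences every input feature is binary (base b present
at position p or not), so the accumulated-local-effects computation reduces
to a centered two-level difference: for each feature, the model is evaluated
with the feature forced to 0 and forced to 1 over a reference sample of
random sequences, and the two level effects are centered by their empirical
frequencies so the frequency-weighted mean effect is zero.  Both model
outputs — predictive mean and predictive variance — are explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .model import TrainedModel
from .sequence_io import ALPHABET
from .synthetic import _random_sequences
from .sequence_io import encode_batch

__all__ = [
    "ALEMatrix",
    "LogoMatrix",
    "GuideEmbedding",
    "ale_explain",
    "ale_for_model",
    "ale_logo",
    "guide_space_coords",
    "embed_2d",
    "cluster_guide_space",
    "ale_to_frame",
    "plot_logo",
]


@dataclass
class ALEMatrix:
    """ALE values of shape (4N, 2 levels, n_outputs).

    ``effects[j, 0, o]`` / ``effects[j, 1, o]`` are the centered effects of
    feature j being absent / present on output o; ``level_freq[j]`` is the
    empirical frequency of level 1.  ``slice_level1(o)`` reshapes the
    present-level effects of output o to a (4, N) base-by-position matrix.
    """

    effects: np.ndarray
    level_freq: np.ndarray
    length: int

    def slice_level1(self, output: int = 0) -> np.ndarray:
        return self.effects[:, 1, output].reshape(4, self.length)

    def position_importance(self, output: int = 0) -> np.ndarray:
        """Mean |level-1 minus level-0 effect| over bases, per position."""
        diff = self.effects[:, 1, output] - self.effects[:, 0, output]
        return np.abs(diff).reshape(4, self.length).mean(axis=0)


@dataclass
class LogoMatrix:
    """Column-stochastic (4, N) matrix of per-position base probabilities."""

    probs: np.ndarray
    temperature: float

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("logo columns must sum to 1")


@dataclass
class GuideEmbedding:
    points: np.ndarray  # (n_guides, 2)
    method: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding coordinates must be finite")


def ale_explain(predict_fn, length: int, pair: bool = False,
                n_synthetic: int = 10000, seed: int = 0) -> ALEMatrix:
    """Two-level ALE of ``predict_fn`` over random synthetic sequences.

    ``predict_fn`` maps a one-hot batch — (M, 4, N) for guides or
    (M, 2, 4, N) for pairs — to an (M, n_outputs) array.  Features are the
    flattened one-hot entries; each is toggled to 0 and to 1 over the whole
    reference sample and the mean predictions are centered by the level
    frequencies.
    """
    rng = np.random.default_rng(seed)
    if pair:
        guides = _random_sequences(n_synthetic, length, rng)
        targets = _random_sequences(n_synthetic, length, rng)
        X = np.stack([encode_batch(guides), encode_batch(targets)], axis=1)
    else:
        X = encode_batch(_random_sequences(n_synthetic, length, rng))
    base = np.asarray(predict_fn(X))
    if base.ndim == 1:
        base = base[:, None]
    n_outputs = base.shape[1]
    flat_shape = X.shape[1:]
    n_features = int(np.prod(flat_shape))
    effects = np.zeros((n_features, 2, n_outputs))
    freq = np.zeros(n_features)
    flat_idx = [np.unravel_index(j, flat_shape) for j in range(n_features)]
    for j, idx in enumerate(flat_idx):
        sel = (slice(None),) + idx
        orig = X[sel].copy()
        X[sel] = 0.0
        a0 = np.asarray(predict_fn(X))
        X[sel] = 1.0
        a1 = np.asarray(predict_fn(X))
        X[sel] = orig
        a0 = a0[:, None] if a0.ndim == 1 else a0
        a1 = a1[:, None] if a1.ndim == 1 else a1
        m0, m1 = a0.mean(axis=0), a1.mean(axis=0)
        p1 = float(orig.mean())
        center = (1 - p1) * m0 + p1 * m1
        effects[j, 0] = m0 - center
        effects[j, 1] = m1 - center
        freq[j] = p1
    return ALEMatrix(effects=effects, level_freq=freq, length=length)


def ale_for_model(model: TrainedModel, n_synthetic: int = 10000,
                  seed: int = 0, n_samples: int | None = None) -> ALEMatrix:
    """ALE of a trained model's (predictive mean, predictive variance)."""

    def predict(X):
        return model.predict_meanvar(X, n_samples=n_samples, seed=seed)

    return ale_explain(predict, model.input_length, pair=model.is_pair,
                       n_synthetic=n_synthetic, seed=seed)


def ale_logo(ale_slice: np.ndarray, t: float = 1.0) -> LogoMatrix:
    """Temperature softmax of a (4, N) effect matrix along the base axis.

    Low temperature sharpens columns toward the argmax base; high temperature
    flattens them toward uniform 0.25.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    ale_slice = np.asarray(ale_slice, dtype=float)
    if ale_slice.ndim != 2 or ale_slice.shape[0] != 4:
        raise ValueError(f"expected a (4, N) matrix, got {ale_slice.shape}")
    z = ale_slice / t
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return LogoMatrix(probs=e / e.sum(axis=0, keepdims=True), temperature=t)


def guide_space_coords(model: TrainedModel, guides) -> np.ndarray:
    """Flattened Hit-or-Miss capsule outputs, one row per guide."""
    coords = model.encode(guides)
    return coords.reshape(coords.shape[0], -1)


def embed_2d(coords: np.ndarray, method: str = "pca", seed: int = 0,
             **kwargs) -> GuideEmbedding:
    """Project guide-space coordinates to 2D with PCA or UMAP."""
    coords = np.asarray(coords, dtype=float)
    if method == "pca":
        points = PCA(n_components=2, random_state=seed).fit_transform(coords)
    elif method == "umap":
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
        points = reducer.fit_transform(coords)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")
    return GuideEmbedding(points=np.asarray(points, dtype=float), method=method)


def cluster_guide_space(coords: np.ndarray, max_d: float = 2.0,
                        method: str = "single") -> np.ndarray:
    """Agglomerative clustering cut at cophenetic distance ``max_d``.

    Returns integer cluster labels (scipy convention, starting at 1).
    Linkage defaults to single; 'ward' is also supported.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise ValueError("cannot cluster an empty set of coordinates")
    if len(coords) == 1:
        return np.array([1])
    if method not in ("single", "ward"):
        raise ValueError(f"unsupported linkage: {method!r}")
    Z = linkage(coords, method=method)
    return fcluster(Z, t=max_d, criterion="distance")


def ale_to_frame(ale: ALEMatrix) -> pd.DataFrame:
    """Tidy TSV-ready table: position, base, effect per output, level-1 slice."""
    rows = []
    for output, name in enumerate(["effect_mean", "effect_variance"][: ale.effects.shape[2]]):
        m = ale.slice_level1(output)
        for b in range(4):
            for p in range(ale.length):
                rows.append(
                    {"position": p, "base": ALPHABET[b], "output": name,
                     "effect": m[b, p]}
                )
    frame = pd.DataFrame(rows)
    return frame.pivot_table(index=["position", "base"], columns="output",
                             values="effect").reset_index()


def plot_logo(logo: LogoMatrix, ax=None, colors=None):
    """Render a sequence logo: stacked letters with heights = probabilities."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle  # noqa: F401  (kept for styling)

    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * logo.probs.shape[1], 2))
    colors = colors or {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    n = logo.probs.shape[1]
    for p in range(n):
        bottom = 0.0
        order = np.argsort(logo.probs[:, p])
        for b in order:
            h = logo.probs[b, p]
            ax.text(p + 0.5, bottom + h / 2, ALPHABET[b], ha="center", va="center",
                    fontsize=14 * max(h, 0.05) / 0.25, color=colors[ALPHABET[b]],
                    fontweight="bold")
            bottom += h
    ax.set_xlim(0, n)
    ax.set_ylim(0, 1)
    ax.set_xlabel("position")
    ax.set_ylabel("probability")
    return ax
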