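"""Synthetic sequence-activity datasets with known ground truth.

The generator emulates the statistical structure the predictive model
assumes: activity is a logistic function of a position-dependent sequence
effect concentrated in a PAM-proximal seed region, observed through
heteroscedastic Gaussian label noise.  Pair datasets additionally damp
activity multiplicatively with mismatches, more strongly for seed-proximal
ones.  Every quantity (true effect f(seq), true noise sd sigma(seq)) is
returned alongside the labels, so calibration tests have an exact reference.

The noise sd of a sequence is a deterministic hash of the sequence mapped
into [sigma_min, sigma_max]; it does not depend on the RNG seed, which keeps
the ground truth well-posed across replicates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, LabeledDataset, encode_batch, encode_pair_batch, scale_activities

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "MismatchModel",
    "simulate_dataset",
    "simulate_pair_dataset",
]

_WEIGHT_SEED = 987654321  # fixes the default effect weights, independent of data seed


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class EffectSpec:
    """Position-dependent sequence effect with a logistic link.

    By default the 5 PAM-proximal (3'-terminal, Cas9-like seed) positions
    carry independent standard-normal per-base weights and every other
    position has weight zero, mirroring the seed-region dominance real
    cleavage data shows.  ``f(seq) = sigmoid(sum_p w[base_p, p])``.
    """

    length: int = 21
    informative_positions: tuple[int, ...] | None = None
    weights: np.ndarray | None = None  # (4, length)
    weight_scale: float = 1.0

    def __post_init__(self):
        if self.informative_positions is None:
            self.informative_positions = tuple(range(self.length - 5, self.length))
        if any(p < 0 or p >= self.length for p in self.informative_positions):
            raise ValueError("informative positions outside sequence length")
        if self.weights is None:
            rng = np.random.default_rng(_WEIGHT_SEED)
            w = np.zeros((4, self.length))
            idx = list(self.informative_positions)
            draw = rng.standard_normal((4, len(idx)))
            # standardize per position: zero mean (the offset is an intercept
            # for one-hot inputs) and unit variance, so the default effect
            # size does not depend on the particular random draw
            draw = (draw - draw.mean(axis=0)) / draw.std(axis=0)
            w[:, idx] = self.weight_scale * draw
            self.weights = w
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4, self.length):
            raise ValueError(f"weights must have shape (4, {self.length})")

    def f(self, onehot: np.ndarray) -> np.ndarray:
        """True activity for a batch of one-hot guides, in (0, 1)."""
        return _sigmoid(np.einsum("bpn,pn->b", onehot, self.weights))


@dataclass
class NoiseSpec:
    """Heteroscedastic Gaussian label noise.

    sigma(seq) is uniform-in-hash over [sigma_min, sigma_max]: the MD5 digest
    of the sequence string is mapped to [0, 1) and rescaled, so a given
    sequence always has the same noise level.
    """

    sigma_min: float = 0.05
    sigma_max: float = 0.15

    def __post_init__(self):
        if not (0 < self.sigma_min <= self.sigma_max):
            raise ValueError("need 0 < sigma_min <= sigma_max")

    def sigma(self, seq: str) -> float:
        h = int.from_bytes(hashlib.md5(seq.encode()).digest()[:8], "big")
        u = h / 2**64
        return self.sigma_min + u * (self.sigma_max - self.sigma_min)

    def sigma_batch(self, seqs) -> np.ndarray:
        return np.array([self.sigma(s) for s in seqs])


@dataclass
class MismatchModel:
    """Multiplicative activity penalty for guide-target mismatches.

    Each mismatched position multiplies activity by exp(-penalty); seed
    positions carry a larger penalty, so at equal mismatch count a
    seed-proximal mismatch always hurts more.
    """

    seed_positions: tuple[int, ...] = field(default_factory=tuple)
    seed_penalty: float = 0.9
    other_penalty: float = 0.25

    def __post_init__(self):
        if self.seed_penalty <= self.other_penalty:
            raise ValueError("seed mismatches must be penalized more than others")
        if self.other_penalty < 0:
            raise ValueError("penalties must be non-negative")

    def multiplier(self, positions) -> float:
        total = sum(
            self.seed_penalty if p in self.seed_positions else self.other_penalty
            for p in positions
        )
        return float(np.exp(-total))


def _random_sequences(n: int, length: int, rng: np.random.Generator, gc_bias: float = 0.0):
    """i.i.d. sequences; gc_bias shifts probability mass toward G/C."""
    p = np.array([1 - gc_bias, 1 + gc_bias, 1 + gc_bias, 1 - gc_bias], dtype=float)
    p /= p.sum()
    idx = rng.choice(4, size=(n, length), p=p)
    return ["".join(ALPHABET[i] for i in row) for row in idx]


def simulate_dataset(
    n: int,
    length: int = 21,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    gc_bias: float = 0.0,
) -> tuple[LabeledDataset, pd.DataFrame]:
    """Simulate a single-guide activity dataset.

    Returns the encoded, [0,1]-rescaled dataset plus a ground-truth table
    with the pre- and post-rescale true effect and noise sd per record.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    effect = effect if effect is not None else EffectSpec(length=length)
    noise = noise if noise is not None else NoiseSpec()
    if effect.length != length:
        raise ValueError(f"effect spec is for length {effect.length}, not {length}")
    rng = np.random.default_rng(seed)
    seqs = _random_sequences(n, length, rng, gc_bias)
    onehot = encode_batch(seqs)
    f = effect.f(onehot)
    sigma = noise.sigma_batch(seqs)
    raw = f + sigma * rng.standard_normal(n)
    labels, scale = scale_activities(raw)
    span = scale.observed_max - scale.observed_min
    truth = pd.DataFrame(
        {
            "sequence": seqs,
            "f_raw": f,
            "sigma_raw": sigma,
            "label_raw": raw,
            "f_scaled": scale.transform(f),
            "sigma_scaled": sigma / span,
            "label_scaled": labels,
        }
    )
    return LabeledDataset(onehot, labels, scale, sequences=seqs), truth


def simulate_pair_dataset(
    n: int,
    length: int = 21,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    mismatch_model: MismatchModel | None = None,
    max_mismatches: int = 6,
    seed: int = 0,
) -> tuple[LabeledDataset, pd.DataFrame]:
    """Simulate a guide-target pair dataset with 0..max_mismatches mutations.

    Targets are guides mutated at uniformly chosen positions; activity is the
    on-target effect times the mismatch multiplier, plus Gaussian noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    effect = effect if effect is not None else EffectSpec(length=length)
    noise = noise if noise is not None else NoiseSpec()
    if mismatch_model is None:
        mismatch_model = MismatchModel(
            seed_positions=tuple(range(length - 5, length))
        )
    rng = np.random.default_rng(seed)
    guides = _random_sequences(n, length, rng)
    onehot_g = encode_batch(guides)
    f_on = effect.f(onehot_g)
    targets, mults, n_mm = [], [], []
    for g in guides:
        m = int(rng.integers(0, max_mismatches + 1))
        pos = sorted(rng.choice(length, size=m, replace=False)) if m else []
        t = list(g)
        for p in pos:
            t[p] = rng.choice([b for b in ALPHABET if b != g[p]])
        targets.append("".join(t))
        mults.append(mismatch_model.multiplier(pos))
        n_mm.append(m)
    mults = np.asarray(mults)
    f = f_on * mults
    sigma = noise.sigma_batch(guides)
    raw = f + sigma * rng.standard_normal(n)
    labels, scale = scale_activities(raw)
    truth = pd.DataFrame(
        {
            "sequence": guides,
            "target": targets,
            "mismatches": n_mm,
            "multiplier": mults,
            "f_raw": f,
            "sigma_raw": sigma,
            "label_scaled": labels,
        }
    )
    inputs = encode_pair_batch(list(zip(guides, targets)))
    return LabeledDataset(inputs, labels, scale, sequences=guides), truth
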