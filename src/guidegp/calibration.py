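"""Predictive-interval calibration and regression-quality metrics.

The central statistic is the empirical coverage

    rho(Y, Yhat, sigma, M) = (1/N) * sum_i 1{ Y_i in [Yhat_i - M sigma_i,
                                                      Yhat_i + M sigma_i] }

evaluated at M = 1, 2, 3 and compared against the Gaussian nominal levels
0.68 / 0.95 / 0.997 (rho_68, rho_95, rho_99.7).  Both interval endpoints are
closed; for continuous predictions the choice is measure-zero.

r^2 here is the coefficient of determination 1 - SS_res / SS_tot (not the
squared correlation), so it can be negative for predictors worse than the
mean; PCC and SCC are the usual Pearson and Spearman coefficients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .model import (
    GPHeadConfig,
    HOMConfig,
    PreprocessorConfig,
    TrainConfig,
    TrainedModel,
    train_model,
)
from .sequence_io import LabeledDataset

__all__ = [
    "CalibrationReport",
    "coverage_rho",
    "regression_metrics",
    "evaluate_model",
    "cross_validate",
    "learning_curve",
]


@dataclass
class CalibrationReport:
    rho_68: float
    rho_95: float
    rho_997: float
    pcc: float
    scc: float
    r2: float
    n: int

    def __post_init__(self):
        if not 0 <= self.rho_68 <= self.rho_95 <= self.rho_997 <= 1:
            raise ValueError("coverage fractions must be nested in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def coverage_rho(Y, Yhat, sigma, M: int = 1) -> float:
    """Fraction of labels inside the closed interval Yhat +/- M * sigma."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (len(Y) == len(Yhat) == len(sigma)):
        raise ValueError("Y, Yhat and sigma must have equal lengths")
    if np.any(sigma <= 0):
        raise ValueError("all predictive standard deviations must be positive")
    if M < 1:
        raise ValueError("M must be >= 1")
    inside = np.abs(Y - Yhat) <= M * sigma
    return float(inside.mean())


def regression_metrics(Y, Yhat) -> dict[str, float]:
    """Determination coefficient, Pearson and Spearman correlations."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if len(Y) != len(Yhat):
        raise ValueError("Y and Yhat must have equal lengths")
    if len(Y) < 3:
        raise ValueError("need at least 3 points for correlation metrics")
    if np.ptp(Y) == 0:
        raise ValueError("Y has zero variance; correlations undefined")
    return {
        "r2": float(r2_score(Y, Yhat)),
        "pcc": float(stats.pearsonr(Y, Yhat).statistic),
        "scc": float(stats.spearmanr(Y, Yhat).statistic),
    }


def evaluate_model(model: TrainedModel, X, Y, n_samples: int | None = None,
                   seed: int = 0) -> CalibrationReport:
    """Predict on a held-out set and summarize calibration + regression quality."""
    pred = model.predict(X, n_samples=n_samples, seed=seed)
    m = regression_metrics(Y, pred.mean)
    return CalibrationReport(
        rho_68=coverage_rho(Y, pred.mean, pred.std, 1),
        rho_95=coverage_rho(Y, pred.mean, pred.std, 2),
        rho_997=coverage_rho(Y, pred.mean, pred.std, 3),
        pcc=m["pcc"],
        scc=m["scc"],
        r2=m["r2"],
        n=len(np.asarray(Y)),
    )


def holdout_calibration_experiment(
    n: int = 3000,
    length: int = 21,
    seed: int = 1,
    test_fraction: float = 0.2,
    pcfg: PreprocessorConfig | None = None,
    hcfg: HOMConfig | None = None,
    gcfg: GPHeadConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> CalibrationReport:
    """End-to-end calibration study on synthetic heteroscedastic data.

    Simulates ``n`` guides of the given length with the default seed-region
    effect and Gaussian noise, trains the default model on the training split
    and reports coverage at 1/2/3 predicted standard deviations plus
    regression metrics on the held-out split.  All randomness (simulation,
    split, training, posterior sampling) derives from ``seed``.
    """
    from .synthetic import simulate_dataset

    data, _ = simulate_dataset(n, length, seed=seed)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    tcfg = tcfg or TrainConfig(seed=seed + 2)
    model = train_model(_subset(data, train_idx), pcfg, hcfg, gcfg, tcfg)
    return evaluate_model(model, data.inputs[test_idx], data.labels[test_idx],
                          seed=seed + 3)


def _subset(data: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    seqs = [data.sequences[i] for i in idx] if data.sequences else None
    return LabeledDataset(data.inputs[idx], data.labels[idx], data.scale,
                          sequences=seqs)


def cross_validate(
    data: LabeledDataset,
    k: int = 10,
    pcfg: PreprocessorConfig | None = None,
    hcfg: HOMConfig | None = None,
    gcfg: GPHeadConfig | None = None,
    tcfg: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[list[CalibrationReport], pd.DataFrame]:
    """Plain random k-fold cross-validation (folds disjoint and exhaustive).

    Returns the per-fold reports plus a two-row mean/sd summary table.
    """
    if k > len(data):
        raise ValueError(f"k={k} exceeds dataset size {len(data)}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(kf.split(np.arange(len(data)))):
        model = train_model(_subset(data, train_idx), pcfg, hcfg, gcfg, tcfg)
        reports.append(
            evaluate_model(model, data.inputs[test_idx], data.labels[test_idx],
                           seed=seed + fold)
        )
    table = pd.DataFrame([r.to_dict() for r in reports])
    summary = pd.DataFrame(
        {"mean": table.mean(axis=0), "sd": table.std(axis=0, ddof=1)}
    ).T
    return reports, summary


def learning_curve(
    data: LabeledDataset,
    fractions=(0.1, 0.3, 1.0),
    test_fraction: float = 0.2,
    pcfg: PreprocessorConfig | None = None,
    hcfg: HOMConfig | None = None,
    gcfg: GPHeadConfig | None = None,
    tcfg: TrainConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train on nested subsets of growing size against one fixed test set.

    Nesting (train(0.1) is a subset of train(0.3), ...) makes the curves
    comparable: each larger model has seen everything the smaller one has.
    Records regression metrics and the mean/median predicted sd per fraction.
    """
    fractions = sorted(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(data))
    n_test = int(round(test_fraction * len(data)))
    test_idx, pool = perm[:n_test], perm[n_test:]
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * len(pool)))
        if n_sub < 10:
            raise ValueError(f"fraction {frac} yields fewer than 10 training examples")
        train_idx = pool[:n_sub]  # prefix of one permutation => nested subsets
        model = train_model(_subset(data, train_idx), pcfg, hcfg, gcfg, tcfg)
        pred = model.predict(data.inputs[test_idx], seed=seed)
        metrics = regression_metrics(data.labels[test_idx], pred.mean)
        rows.append(
            {
                "fraction": frac,
                "n_train": n_sub,
                **metrics,
                "mean_sigma": float(pred.std.mean()),
                "median_sigma": float(np.median(pred.std)),
            }
        )
    return pd.DataFrame(rows)
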