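"""Brain-age prediction: leakage-free repeated nested-CV SVR and bias metrics.

Chronological age is predicted from a feature block with an RBF-kernel
support vector regression.  The protocol is k-fold cross-validation (folds
stratified by age, regenerated per repeat) repeated r times; inside every
outer training fold the features are scaled with a robust median/IQR scaler
and the SVR hyperparameters (penalty C, kernel width gamma, tube width
epsilon) are tuned by an inner grid search scored by MAE.  Scaling and tuning
never see the held-out fold.

Accuracy is summarized per test fold by five statistics: MAE, RMSE, Pearson r
between true and predicted age, prediction R^2, and the age-bias Spearman rho
between the prediction error (predicted - true) and true age; values are
reported as the mean over all folds and repeats +/- the SD of the per-repeat
means.  The brain-age gap Delta = predicted - chronological age (positive =
older-appearing brain) is averaged over repeats per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.preprocessing import RobustScaler
from sklearn.svm import SVR

from .features import BLOCK_NAMES, FeatureTable
from .harmonize import harmonize

__all__ = [
    "CVConfig",
    "PredictionSet",
    "MetricsReport",
    "robust_scale",
    "age_stratified_folds",
    "nested_cv_svr",
    "compute_metrics",
    "brain_age_delta",
    "run_experiment",
    "METRIC_NAMES",
]

METRIC_NAMES = ("mae", "rmse", "r", "r2", "rho")


@dataclass
class CVConfig:
    """Cross-validation protocol and SVR hyperparameter grid.

    Defaults follow the evaluation protocol: 10 outer folds x 10 repeats
    (100 outer models per configuration), 5 inner folds, grid C in
    {0.1, 1, 10, 100}, gamma in {0.1, 1, 10}/n_features, epsilon in
    {0.1, 1, 2} years.  Ties in inner MAE break toward the smallest C, then
    gamma, then epsilon.  ``seed`` fixes all randomness.
    """

    n_folds: int = 10
    n_repeats: int = 10
    inner_folds: int = 5
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_scale_grid: tuple[float, ...] = (0.1, 1.0, 10.0)  # multiplied by 1/d
    epsilon_grid: tuple[float, ...] = (0.1, 1.0, 2.0)
    seed: int = 0
    n_strat_bins: int | None = None  # defaults to n_folds

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1 or self.inner_folds < 2:
            raise ValueError("n_repeats >= 1 and inner_folds >= 2 required")
        if not (self.c_grid and self.gamma_scale_grid and self.epsilon_grid):
            raise ValueError("hyperparameter grids must be non-empty")

    @property
    def strat_bins(self) -> int:
        return self.n_strat_bins if self.n_strat_bins is not None else self.n_folds


@dataclass
class PredictionSet:
    """Out-of-fold predictions: one row per (repeat, fold, subject)."""

    frame: pd.DataFrame  # repeat, fold, subject, age, predicted, C, gamma, epsilon

    def __post_init__(self) -> None:
        required = {"repeat", "fold", "subject", "age", "predicted"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"prediction frame missing columns: {sorted(missing)}")
        if not np.isfinite(self.frame["predicted"].to_numpy(dtype=float)).all():
            raise ValueError("predictions must be finite")
        per_repeat = self.frame.groupby("repeat")["subject"].agg(["count", "nunique"])
        if (per_repeat["count"] != per_repeat["nunique"]).any():
            raise ValueError("every subject must be predicted exactly once per repeat")

    @property
    def n_outer_models(self) -> int:
        return len(self.frame.groupby(["repeat", "fold"]))


@dataclass
class MetricsReport:
    """Per-fold, per-repeat and pooled accuracy statistics."""

    per_fold: pd.DataFrame  # repeat, fold + METRIC_NAMES
    per_repeat: pd.DataFrame  # repeat x METRIC_NAMES (mean over folds)
    summary: pd.DataFrame  # METRIC_NAMES x {mean, sd}


def robust_scale(
    train: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Median/IQR scaling fitted on training rows only.

    Returns the scaled training and application matrices plus the fitted
    per-feature medians and IQRs (25th-75th percentile, linear-interpolation
    quantiles; an IQR of 0 is replaced by a scale of 1, so a constant feature
    maps to all zeros).
    """
    scaler = RobustScaler(quantile_range=(25.0, 75.0)).fit(np.asarray(train, dtype=float))
    return (
        scaler.transform(train),
        scaler.transform(np.asarray(apply_to, dtype=float)),
        scaler.center_,
        scaler.scale_,
    )


def age_stratified_folds(ages: np.ndarray, cfg: CVConfig) -> np.ndarray:
    """Age-stratified fold assignment, one row per repeat.

    Ages are cut into quantile bins; within each bin subjects are shuffled
    (seeded per repeat) and dealt round-robin across folds, with the dealing
    position carried across bins so fold sizes differ by at most one.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if cfg.n_folds > n:
        raise ValueError(f"n_folds={cfg.n_folds} exceeds the {n} subjects available")
    n_bins = min(cfg.strat_bins, n)
    edges = np.quantile(ages, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_id = np.searchsorted(edges, ages, side="right")
    out = np.empty((cfg.n_repeats, n), dtype=int)
    for r in range(cfg.n_repeats):
        rng = np.random.default_rng([int(cfg.seed), 101, r])
        position = 0
        for b in np.unique(bin_id):
            idx = np.flatnonzero(bin_id == b)
            rng.shuffle(idx)
            for i in idx:
                out[r, i] = position % cfg.n_folds
                position += 1
    return out


def _grid(cfg: CVConfig, n_features: int):
    # product order = tie-break order: smallest C, then gamma, then epsilon
    for c, gs, e in product(
        sorted(cfg.c_grid), sorted(cfg.gamma_scale_grid), sorted(cfg.epsilon_grid)
    ):
        yield c, gs / n_features, e


def nested_cv_svr(table: FeatureTable, cfg: CVConfig | None = None) -> PredictionSet:
    """Repeated age-stratified nested-CV SVR brain-age prediction.

    One model is refit per (repeat, outer fold) with hyperparameters chosen
    by inner-CV MAE; robust scaling is fit on the training rows of each
    (inner or outer) split only.
    """
    cfg = cfg or CVConfig()
    X = table.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("at least 2 features are required")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    y = table.covariates["age"].to_numpy(dtype=float)
    subjects = table.values.index.to_numpy()
    d = X.shape[1]
    folds = age_stratified_folds(y, cfg)

    rows = []
    for r in range(cfg.n_repeats):
        for f in range(cfg.n_folds):
            test = folds[r] == f
            train = ~test
            Xtr, ytr = X[train], y[train]
            # inner splits and their scaled matrices are shared by all candidates
            inner = KFold(
                n_splits=cfg.inner_folds,
                shuffle=True,
                random_state=int((cfg.seed * 100003 + r * 1009 + f) % 2**31),
            )
            splits = []
            for itr, ival in inner.split(Xtr):
                Xi, Xv, _, _ = robust_scale(Xtr[itr], Xtr[ival])
                splits.append((Xi, ytr[itr], Xv, ytr[ival]))
            best = None
            for c, gamma, eps in _grid(cfg, d):
                maes = [
                    np.abs(
                        SVR(C=c, gamma=gamma, epsilon=eps).fit(Xi, yi).predict(Xv) - yv
                    ).mean()
                    for Xi, yi, Xv, yv in splits
                ]
                score = float(np.mean(maes))
                if best is None or score < best[0]:
                    best = (score, c, gamma, eps)
            _, c, gamma, eps = best
            Xtr_s, Xte_s, _, _ = robust_scale(Xtr, X[test])
            model = SVR(C=c, gamma=gamma, epsilon=eps).fit(Xtr_s, ytr)
            pred = model.predict(Xte_s)
            for s, age, p in zip(subjects[test], y[test], pred):
                rows.append(
                    {
                        "repeat": r,
                        "fold": f,
                        "subject": s,
                        "age": age,
                        "predicted": p,
                        "C": c,
                        "gamma": gamma,
                        "epsilon": eps,
                    }
                )
    return PredictionSet(pd.DataFrame(rows))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan  # undefined, never silently 0
    return float(stats.pearsonr(a, b).statistic)


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def _fold_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    err = yhat - y
    ss_tot = ((y - y.mean()) ** 2).sum()
    return {
        "mae": float(np.abs(err).mean()),
        "rmse": float(np.sqrt((err**2).mean())),
        "r": _safe_pearson(y, yhat),
        "r2": float(1 - (err**2).sum() / ss_tot) if ss_tot > 0 else np.nan,
        "rho": _safe_spearman(err, y),
    }


def compute_metrics(predictions: PredictionSet) -> MetricsReport:
    """Five accuracy/bias statistics per test fold, with the table convention
    mean (over all folds and repeats) +/- SD (across per-repeat means)."""
    recs = []
    for (r, f), grp in predictions.frame.groupby(["repeat", "fold"]):
        y = grp["age"].to_numpy(dtype=float)
        if len(y) < 2:
            raise ValueError("metrics need at least 2 subjects per fold")
        recs.append(
            {"repeat": r, "fold": f}
            | _fold_metrics(y, grp["predicted"].to_numpy(dtype=float))
        )
    per_fold = pd.DataFrame(recs)
    per_repeat = per_fold.groupby("repeat")[list(METRIC_NAMES)].mean()
    summary = pd.DataFrame(
        {
            "mean": per_fold[list(METRIC_NAMES)].mean(),
            "sd": per_repeat.std(ddof=1) if len(per_repeat) > 1 else np.nan,
        }
    )
    return MetricsReport(per_fold=per_fold, per_repeat=per_repeat, summary=summary)


def brain_age_delta(predictions: PredictionSet) -> pd.Series:
    """Brain-age gap per subject: predicted - chronological age, averaged
    over repeats.  Positive values indicate an older-appearing brain."""
    frame = predictions.frame
    delta = frame["predicted"] - frame["age"]
    return delta.groupby(frame["subject"]).mean().rename("delta")


def run_experiment(
    tables: Mapping[str, FeatureTable],
    strategy: str = "none",
    cfg: CVConfig | None = None,
    batch_key: str = "site",
    covariate_keys: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Evaluate feature-block configurations under one harmonization strategy.

    ``tables`` maps block name (DAT, NET, SERT, MEF, SMF, MMF) to its
    assembled FeatureTable.  Returns one row per block with the pooled
    mean +/- SD of each metric and the number of outer models fitted.
    """
    cfg = cfg or CVConfig()
    rows = []
    order = [b for b in BLOCK_NAMES if b in tables] + [
        b for b in tables if b not in BLOCK_NAMES
    ]
    for block in order:
        harmonized = harmonize(
            tables[block], strategy, batch_key=batch_key, covariate_keys=covariate_keys
        )
        preds = nested_cv_svr(harmonized, cfg)
        report = compute_metrics(preds)
        row = {"block": block, "strategy": strategy, "n_outer_models": preds.n_outer_models}
        for m in METRIC_NAMES:
            row[m] = report.summary.loc[m, "mean"]
            row[f"{m}_sd"] = report.summary.loc[m, "sd"]
        rows.append(row)
    return pd.DataFrame(rows)
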