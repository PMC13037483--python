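"""Model validation: metric suite, leave-group-out CV, residual tables.

Metrics follow the usual chemometric definitions: MSE = SS_res/n,
RMSE = sqrt(MSE), R2 = 1 - SS_res/SS_tot, Adj R2 = 1 - (1-R2)(n-1)/(n-p-1),
SE = sample standard deviation of the residuals (n-1 denominator), plus the
Pearson product-moment correlation between experimental and predicted RT.
Residuals are e = y_exp - y_pred in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import DescriptorTable, Partition

__all__ = ["MetricSet", "CVResult", "compute_metrics", "lgo_cv", "evaluate_model"]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class MetricSet:
    n: int
    p: int
    r2: float
    adj_r2: float          # nan when n <= p + 1
    rmse: float            # minutes
    se: float              # minutes
    mse: float             # minutes^2
    pearson_r: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "p": self.p,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "se": self.se,
            "mse": self.mse,
            "pearson_r": self.pearson_r,
        }


@dataclass
class CVResult:
    groups: np.ndarray          # per-row group id
    y_pred_oof: np.ndarray      # out-of-fold predictions, minutes
    q2: float
    rmsecv: float               # minutes
    fold_seed: int


def compute_metrics(y_exp: np.ndarray, y_pred: np.ndarray, p: int) -> MetricSet:
    """Full metric set for one model on one partition.

    p is the number of independent variables entering the model (used only
    by the adjusted R2).  Raises if y_exp has zero variance; warns and
    reports NaN for Adj R2 when n <= p + 1.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape:
        raise ValidationError("y_exp and y_pred must have equal length")
    n = y_exp.size
    if n < 2:
        raise ValidationError("need at least 2 samples")
    resid = y_exp - y_pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if ss_tot <= 0:
        raise ValidationError("y_exp has zero variance; R2 undefined")
    mse = ss_res / n
    rmse = float(np.sqrt(mse))
    r2 = 1.0 - ss_res / ss_tot
    if n > p + 1:
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        warnings.warn("n <= p + 1: adjusted R2 omitted", stacklevel=2)
        adj_r2 = float("nan")
    se = float(np.std(resid, ddof=1))
    if np.ptp(y_pred) == 0:   # constant predictions: correlation undefined
        pearson = 0.0
    else:
        pearson = float(stats.pearsonr(y_exp, y_pred).statistic)
    return MetricSet(n=n, p=p, r2=r2, adj_r2=adj_r2, rmse=rmse, se=se, mse=mse,
                     pearson_r=pearson)


def lgo_cv(
    X: np.ndarray,
    y: np.ndarray,
    fit_fn: Callable[[np.ndarray, np.ndarray], object],
    group_size: int = 7,
    seed: int = 0,
) -> CVResult:
    """Leave-group-out cross-validation with random groups.

    Rows are shuffled with the seed into ceil(n/group_size) contiguous
    groups; for each group the model (scaler included, via fit_fn) is refit
    on the remainder and the group predicted once.  Q2 = 1 - PRESS/TSS,
    RMSECV = sqrt(PRESS/n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2 * group_size:
        raise ValidationError(f"lgo_cv requires n >= 2 * group_size = {2 * group_size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_groups = int(np.ceil(n / group_size))
    groups = np.empty(n, dtype=int)
    y_oof = np.empty(n)
    for g, fold in enumerate(np.array_split(order, n_groups)):
        groups[fold] = g
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        try:
            model = fit_fn(X[mask], y[mask])
            y_oof[fold] = np.asarray(model.predict(X[fold]), dtype=float)
        except Exception as exc:
            raise ValidationError(f"model failed in fold {g}: {exc}") from exc
    press = float(np.sum((y - y_oof) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return CVResult(
        groups=groups,
        y_pred_oof=y_oof,
        q2=1.0 - press / tss,
        rmsecv=float(np.sqrt(press / n)),
        fold_seed=seed,
    )


def evaluate_model(
    model,
    table: DescriptorTable,
    partition: Partition,
) -> tuple[MetricSet, MetricSet | None, pd.DataFrame]:
    """Train/test metric blocks plus the full residual table.

    p is taken from the model's input dimension.  An empty test partition
    yields a warning and a None test block.
    """
    p = model.n_inputs
    y = table.response
    pred = np.asarray(model.predict(table.values), dtype=float)
    rows = []
    for label, idx in (
        ("train", partition.train_idx),
        ("val", partition.val_idx),
        ("test", partition.test_idx),
    ):
        for i in idx:
            rows.append(
                {
                    "id": table.compound_ids[i],
                    "y_exp": y[i],
                    "y_pred": pred[i],
                    "residual": y[i] - pred[i],
                    "partition": label,
                }
            )
    residuals = pd.DataFrame(rows)
    train_metrics = compute_metrics(y[partition.train_idx], pred[partition.train_idx], p)
    if len(partition.test_idx) == 0:
        warnings.warn("empty test partition: test block omitted", stacklevel=2)
        test_metrics = None
    else:
        test_metrics = compute_metrics(y[partition.test_idx], pred[partition.test_idx], p)
    return train_metrics, test_metrics, residuals
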