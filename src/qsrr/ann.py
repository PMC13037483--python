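"""Single-hidden-layer MLP trained by Levenberg-Marquardt for RT regression.

Topology is d inputs -> h tanh units -> 1 linear output, so a 7-4-1 network
carries 4*(7+1) + (4+1) = 37 weights.  Each epoch solves the damped
Gauss-Newton system (J'J + lambda I) dw = J'e on the full training batch,
accepting the step only if the training SSE decreases; validation RMSE is
tracked for early stopping and the weights at the best validation error are
returned.  Inputs and the response are z-scored with training statistics,
so `forward` operates in scaled units while `ANNModel.predict` returns
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pretreatment import Scaler, fit_scaler

__all__ = [
    "ANNConfig",
    "ANNModel",
    "SensitivityReport",
    "forward",
    "train_lm",
    "select_architecture",
    "multi_restart",
    "sensitivity",
    "jacobian",
]

_EPOCH_CAP = 200
_LAMBDA_MAX = 1e10
_RETRY_CAP = 30


class ANNError(ValueError):
    pass


@dataclass(frozen=True)
class ANNConfig:
    hidden_range: tuple[int, int] = (2, 10)
    max_epochs: int = 150          # hard cap 200
    patience: int = 10
    lambda0: float = 0.01          # initial LM damping
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    n_restarts: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hidden_range
        if not (1 <= lo <= hi <= 50):
            raise ANNError("hidden_range must lie within [1, 50]")
        if self.patience < 1:
            raise ANNError("patience must be >= 1")
        if self.lambda0 <= 0:
            raise ANNError("lambda0 must be > 0")
        if self.max_epochs > _EPOCH_CAP:
            raise ANNError(f"max_epochs capped at {_EPOCH_CAP}")


@dataclass
class ANNModel:
    hidden_units: int
    input_weights: np.ndarray     # h x (d+1), bias first column
    output_weights: np.ndarray    # (h+1,), bias first
    x_scaler: Scaler
    y_mean: float
    y_sd: float
    best_val_rmse: float          # minutes
    epochs_run: int
    restart_seed: int
    val_history: list[float] = field(default_factory=list)   # minutes per epoch

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1] - 1

    @property
    def n_parameters(self) -> int:
        h, d1 = self.input_weights.shape
        return h * d1 + (h + 1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self.x_scaler.transform(X)
        return self.y_mean + self.y_sd * forward(self, Xs)


def forward(model: ANNModel, x: np.ndarray) -> np.ndarray | float:
    """Network function in scaled units: w2 . [1, tanh(W1 [1, x])]."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_inputs:
        raise ANNError(
            f"expected {model.n_inputs} inputs, got {X.shape[1]}"
        )
    A = np.tanh(X @ model.input_weights[:, 1:].T + model.input_weights[:, 0])
    out = model.output_weights[0] + A @ model.output_weights[1:]
    return float(out[0]) if single else out


def _unpack(w: np.ndarray, h: int, d: int):
    W1 = w[: h * (d + 1)].reshape(h, d + 1)
    w2 = w[h * (d + 1) :]
    return W1, w2


def _net_forward(w: np.ndarray, X: np.ndarray, h: int):
    d = X.shape[1]
    W1, w2 = _unpack(w, h, d)
    A = np.tanh(X @ W1[:, 1:].T + W1[:, 0])
    return w2[0] + A @ w2[1:], A


def jacobian(w: np.ndarray, X: np.ndarray, h: int) -> np.ndarray:
    """Analytic Jacobian of the network output w.r.t. the flat weight vector."""
    n, d = X.shape
    W1, w2 = _unpack(w, h, d)
    A = np.tanh(X @ W1[:, 1:].T + W1[:, 0])      # n x h
    dA = 1.0 - A**2
    X1 = np.hstack([np.ones((n, 1)), X])         # n x (d+1)
    J = np.empty((n, w.size))
    # d out / d W1[k, j] = w2[k+1] * (1 - A_k^2) * x1_j
    for k in range(h):
        J[:, k * (d + 1) : (k + 1) * (d + 1)] = (w2[k + 1] * dA[:, k])[:, None] * X1
    J[:, h * (d + 1)] = 1.0
    J[:, h * (d + 1) + 1 :] = A
    return J


def train_lm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hidden: int,
    config: ANNConfig = ANNConfig(),
    seed: int | None = None,
) -> ANNModel:
    """Levenberg-Marquardt training with validation early stopping.

    Weight init is U(-0.5, 0.5) from a seeded generator; an epoch that
    cannot find an accepted step before the damping exceeds 1e10 ends
    training (converged stall, not an error).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_val = np.asarray(y_val, dtype=float)
    n, d = X_train.shape
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    scaler = fit_scaler(X_train)
    Xs = scaler.transform(X_train)
    Xvs = scaler.transform(X_val)
    y_mean = float(y_train.mean())
    y_sd = float(y_train.std(ddof=1))
    if y_sd <= 0:
        raise ANNError("training response is constant")
    ys = (y_train - y_mean) / y_sd
    yvs = (y_val - y_mean) / y_sd

    n_par = hidden * (d + 1) + (hidden + 1)
    w = rng.uniform(-0.5, 0.5, size=n_par)
    lam = config.lambda0

    def sse(weights):
        out, _ = _net_forward(weights, Xs, hidden)
        return float(np.sum((ys - out) ** 2)), out

    cur_sse, _ = sse(w)
    best_w = w.copy()
    best_val = np.inf
    stall = 0
    val_history: list[float] = []
    epochs_run = 0
    for epoch in range(config.max_epochs):
        accepted = False
        for _ in range(_RETRY_CAP):
            out, _ = _net_forward(w, Xs, hidden)
            e = ys - out
            J = jacobian(w, Xs, hidden)
            A = J.T @ J + lam * np.eye(n_par)
            g = J.T @ e
            try:
                step = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, g, rcond=None)[0]
            cand = w + step
            cand_sse, _ = sse(cand)
            if not np.isfinite(cand_sse):
                raise ANNError("non-finite training loss")
            if cand_sse < cur_sse:
                assert cand_sse <= cur_sse  # accepted steps never increase SSE
                w = cand
                cur_sse = cand_sse
                lam = max(lam * config.lambda_down, 1e-12)
                accepted = True
                break
            lam *= config.lambda_up
            if lam > _LAMBDA_MAX:
                break
        epochs_run = epoch + 1
        out_v, _ = _net_forward(w, Xvs, hidden)
        val_rmse = float(np.sqrt(np.mean((yvs - out_v) ** 2))) * y_sd
        val_history.append(val_rmse)
        if val_rmse < best_val - 1e-15:
            best_val = val_rmse
            best_w = w.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        if not accepted:
            break   # converged stall: no further step can be found

    W1, w2 = _unpack(best_w, hidden, d)
    return ANNModel(
        hidden_units=hidden,
        input_weights=W1,
        output_weights=w2,
        x_scaler=scaler,
        y_mean=y_mean,
        y_sd=y_sd,
        best_val_rmse=best_val,
        epochs_run=epochs_run,
        restart_seed=seed,
        val_history=val_history,
    )


def _spawn_seeds(master: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(count)]


def multi_restart(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hidden: int,
    config: ANNConfig = ANNConfig(),
) -> tuple[ANNModel, pd.DataFrame]:
    """Train n_restarts independently seeded networks; keep the best.

    Returns the lowest-validation-RMSE model and a per-restart table with
    mean and sd aggregate rows (RMSEs in minutes).
    """
    seeds = _spawn_seeds(config.seed, config.n_restarts)
    rows = []
    best_model = None
    for i, s in enumerate(seeds):
        m = train_lm(X_train, y_train, X_val, y_val, hidden, config, seed=s)
        train_rmse = float(np.sqrt(np.mean((y_train - m.predict(X_train)) ** 2)))
        rows.append(
            {
                "restart": i,
                "seed": s,
                "train_rmse": train_rmse,
                "val_rmse": m.best_val_rmse,
                "epochs": m.epochs_run,
            }
        )
        if best_model is None or m.best_val_rmse < best_model.best_val_rmse:
            best_model = m
    table = pd.DataFrame(rows)
    agg = pd.DataFrame(
        {
            "restart": ["mean", "sd"],
            "seed": [np.nan, np.nan],
            "train_rmse": [table["train_rmse"].mean(), table["train_rmse"].std(ddof=1)],
            "val_rmse": [table["val_rmse"].mean(), table["val_rmse"].std(ddof=1)],
            "epochs": [table["epochs"].mean(), table["epochs"].std(ddof=1)],
        }
    )
    return best_model, pd.concat([table, agg], ignore_index=True)


def select_architecture(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ANNConfig = ANNConfig(),
) -> tuple[int, pd.DataFrame]:
    """Scan hidden-unit counts; pick the argmin of median validation RMSE.

    The scan uses a reduced number of restarts (>= 3); ties break toward
    fewer neurons.
    """
    lo, hi = config.hidden_range
    if lo > hi:
        raise ANNError("empty hidden_range")
    scan_restarts = max(3, config.n_restarts // 5)
    seeds = _spawn_seeds(config.seed, scan_restarts)
    y_val = np.asarray(y_val, dtype=float)
    rows = []
    best_h, best_med = None, np.inf
    for h in range(lo, hi + 1):
        vals, r2s = [], []
        for s in seeds:
            m = train_lm(X_train, y_train, X_val, y_val, h, config, seed=s)
            vals.append(m.best_val_rmse)
            pred = m.predict(X_val)
            tss = float(np.sum((y_val - y_val.mean()) ** 2))
            r2s.append(1.0 - float(np.sum((y_val - pred) ** 2)) / tss if tss else np.nan)
        med = float(np.median(vals))
        rows.append(
            {
                "hidden": h,
                "median_val_rmse": med,
                "median_val_r2": float(np.median(r2s)),
            }
        )
        if med < best_med - 1e-15:
            best_med, best_h = med, h
    return best_h, pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Mean |delta predicted RT| (minutes) per descriptor and perturbation."""

    table: pd.DataFrame   # columns: descriptor, one per delta, mean_abs_change, rank

    def ranks(self) -> dict[str, int]:
        return dict(zip(self.table["descriptor"], self.table["rank"]))


def sensitivity(
    models: list[ANNModel],
    X: np.ndarray,
    deltas: tuple[float, ...] = (-0.10, -0.05, 0.05, 0.10),
    descriptor_names: list[str] | None = None,
) -> SensitivityReport:
    """Perturb each standardized input by (1 + delta), others fixed.

    Records the mean absolute change in predicted RT (minutes) over rows and
    model realizations; descriptors are ranked by the mean across deltas
    (rank 1 = most influential).  X is in scaled units.
    """
    if not models:
        raise ANNError("sensitivity requires at least one model")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    names = descriptor_names or [f"x{j + 1}" for j in range(d)]
    effects = np.zeros((d, len(deltas)))
    for m in models:
        base = np.asarray(forward(m, X))
        for j in range(d):
            for di, delta in enumerate(deltas):
                Xp = X.copy()
                Xp[:, j] = X[:, j] * (1.0 + delta)
                pred = np.asarray(forward(m, Xp))
                effects[j, di] += np.mean(np.abs(pred - base)) * m.y_sd
    effects /= len(models)
    mean_abs = effects.mean(axis=1)
    order = np.argsort(-mean_abs, kind="stable")
    rank = np.empty(d, dtype=int)
    rank[order] = np.arange(1, d + 1)
    tbl = pd.DataFrame({"descriptor": names})
    for di, delta in enumerate(deltas):
        tbl[f"delta_{delta:+.2f}"] = effects[:, di]
    tbl["mean_abs_change"] = mean_abs
    tbl["rank"] = rank
    return SensitivityReport(table=tbl)
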