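"""Descriptor pre-treatment and autoscaling.

Three-stage filter applied before any model fitting: drop zero-variance
columns, drop near-constant columns (modal value in >= 95% of rows), then
scan pairs with |Pearson r| above the threshold (default 0.90) and drop one
member of each.  The survivor of a correlated pair is the column more
correlated with the response (falling back to the earlier column), which
keeps predictive signal while making removal deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import DescriptorTable

__all__ = ["PretreatReport", "Scaler", "pretreat", "fit_scaler", "apply_scaler"]


class PretreatError(ValueError):
    pass


@dataclass
class PretreatReport:
    removed_constant: list[str]
    removed_near_constant: list[str]
    removed_correlated: list[tuple[str, str, float]]   # (kept, dropped, r)
    surviving: list[str]

    def all_removed(self) -> list[str]:
        return (
            self.removed_constant
            + self.removed_near_constant
            + [d for _, d, _ in self.removed_correlated]
        )


@dataclass
class Scaler:
    """Column z-score statistics fitted on a training row set (n-1 sd)."""

    means: np.ndarray
    sds: np.ndarray
    fitted_on: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.sds + self.means


def _modal_fraction(col: np.ndarray) -> float:
    _, counts = np.unique(col, return_counts=True)
    return counts.max() / col.size


def pretreat(
    table: DescriptorTable,
    r_threshold: float = 0.90,
    near_constant_fraction: float = 0.95,
    response_aware: bool = True,
) -> tuple[DescriptorTable, PretreatReport]:
    """Remove constant, near-constant and highly correlated descriptors.

    Correlations (both descriptor-descriptor and descriptor-response) are
    computed on training rows only when the table carries partition labels,
    so the filter never sees held-out compounds.
    """
    if table.n < 3:
        raise PretreatError("pretreat requires at least 3 rows")
    X = table.values
    names = table.descriptor_names
    if table.partition_labels is not None:
        rows = np.flatnonzero(table.partition_labels == "train")
        if rows.size < 3:
            rows = np.arange(table.n)
    else:
        rows = np.arange(table.n)

    ptp = X.max(axis=0) - X.min(axis=0)
    const = [names[j] for j in range(table.k) if ptp[j] == 0.0]
    alive = [j for j in range(table.k) if ptp[j] > 0.0]

    near = [
        names[j]
        for j in alive
        if _modal_fraction(X[:, j]) >= near_constant_fraction
    ]
    near_set = set(near)
    alive = [j for j in alive if names[j] not in near_set]

    removed_corr: list[tuple[str, str, float]] = []
    if alive:
        sub = X[np.ix_(rows, alive)]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
            if corr.ndim == 0:
                corr = corr.reshape(1, 1)
            y = table.response[rows]
            ysd = y.std(ddof=1)
            if ysd > 0:
                yc = (y - y.mean()) / ysd
                sub_sd = sub.std(axis=0, ddof=1)
                r_y = ((sub - sub.mean(axis=0)) / sub_sd).T @ yc / (rows.size - 1)
            else:
                r_y = np.zeros(len(alive))
        corr = np.nan_to_num(corr, nan=0.0)
        r_y = np.nan_to_num(np.asarray(r_y), nan=0.0)
        dead = np.zeros(len(alive), dtype=bool)
        for i in range(len(alive)):
            if dead[i]:
                continue
            for j in range(i + 1, len(alive)):
                if dead[j]:
                    continue
                r = corr[i, j]
                if abs(r) > r_threshold:
                    if response_aware and abs(r_y[j]) > abs(r_y[i]):
                        keep, drop = j, i
                    else:
                        keep, drop = i, j
                    dead[drop] = True
                    removed_corr.append(
                        (names[alive[keep]], names[alive[drop]], float(r))
                    )
                    if drop == i:
                        break
        alive = [alive[i] for i in range(len(alive)) if not dead[i]]

    if not alive:
        raise PretreatError("no descriptors survive pre-treatment")

    surviving = [names[j] for j in alive]
    reduced = table.select_columns(surviving)
    report = PretreatReport(
        removed_constant=const,
        removed_near_constant=near,
        removed_correlated=removed_corr,
        surviving=surviving,
    )
    return reduced, report


def fit_scaler(table: DescriptorTable | np.ndarray, rows=None) -> Scaler:
    """Fit z-score statistics on the given rows (default: all rows)."""
    X = table.values if isinstance(table, DescriptorTable) else np.asarray(table, float)
    if rows is None:
        rows = np.arange(X.shape[0])
    rows = np.asarray(rows, dtype=int)
    sub = X[rows]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=1)
    if np.any(sds <= 0) or np.any(~np.isfinite(sds)):
        bad = np.flatnonzero((sds <= 0) | ~np.isfinite(sds))
        raise PretreatError(
            f"zero-variance column(s) at positions {bad.tolist()}: run pretreat first"
        )
    return Scaler(means=means, sds=sds, fitted_on=rows)


def apply_scaler(scaler: Scaler, table: DescriptorTable | np.ndarray):
    """Transform a table or matrix with training statistics."""
    if isinstance(table, DescriptorTable):
        out = table.select_columns(table.descriptor_names)
        out.values = scaler.transform(table.values)
        return out
    return scaler.transform(table)
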