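"""Loading, validation and partitioning of retention-time datasets.

The packaged fixture is the 75-compound GC retention-time table (HP-5
column, minutes) with its printed 60/15 train/test split.  User-supplied
descriptor matrices arrive as delimited text: one ID column, one response
column (RT in minutes) and any number of named numeric descriptor columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "DescriptorTable",
    "Partition",
    "DatasetError",
    "load_fixture",
    "fixture_frame",
    "load_descriptor_table",
    "write_table",
    "write_predictions",
    "make_partition",
]

_FIXTURE_NAME = "drug_rt_table.csv"


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset inputs."""


@dataclass(frozen=True)
class CompoundRecord:
    """One drug from the packaged retention-time table."""

    index: int
    name: str
    rt_exp: float          # minutes
    category: str
    mw: float              # g/mol
    xlogp3: float
    hbd: int
    partition: str         # "train" or "test"

    def __post_init__(self) -> None:
        if not self.name:
            raise DatasetError(f"row {self.index}: empty compound name")
        if not (self.rt_exp > 0):
            raise DatasetError(f"row {self.index} ({self.name}): rt_exp must be > 0")
        if not (self.mw > 0):
            raise DatasetError(f"row {self.index} ({self.name}): mw must be > 0")
        if self.hbd < 0:
            raise DatasetError(f"row {self.index} ({self.name}): hbd must be >= 0")
        if self.partition not in ("train", "test"):
            raise DatasetError(
                f"row {self.index} ({self.name}): partition must be train/test"
            )


@dataclass
class DescriptorTable:
    """A compounds x descriptors matrix aligned with an RT response vector."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray                       # shape (n, K), float
    response: np.ndarray                     # shape (n,), minutes
    partition_labels: np.ndarray | None = None   # over {"train","val","test"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n, k = self.values.shape
        if len(self.compound_ids) != n:
            raise DatasetError("compound_ids length does not match value rows")
        if len(self.descriptor_names) != k:
            raise DatasetError("descriptor_names length does not match value columns")
        if len(set(self.descriptor_names)) != k:
            dupes = sorted(
                {d for d in self.descriptor_names if self.descriptor_names.count(d) > 1}
            )
            raise DatasetError(f"duplicate descriptor names: {dupes}")
        if self.response.shape != (n,):
            raise DatasetError("response is not aligned row-wise with values")
        if not np.isfinite(self.values).all():
            raise DatasetError("descriptor matrix contains missing/non-finite entries")
        if not np.isfinite(self.response).all():
            raise DatasetError("response contains missing/non-finite entries")
        if self.partition_labels is not None:
            self.partition_labels = np.asarray(self.partition_labels, dtype=object)
            if self.partition_labels.shape != (n,):
                raise DatasetError("partition labels not aligned with rows")
            bad = set(self.partition_labels) - {"train", "val", "test"}
            if bad:
                raise DatasetError(f"unknown partition labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {d: i for i, d in enumerate(self.descriptor_names)}
        missing = [d for d in names if d not in pos]
        if missing:
            raise DatasetError(f"unknown descriptor names: {missing}")
        return np.array([pos[d] for d in names], dtype=int)

    def select_columns(self, names: Sequence[str]) -> "DescriptorTable":
        idx = self.column_index(names)
        return replace(
            self,
            descriptor_names=list(names),
            values=self.values[:, idx].copy(),
        )

    def select_rows(self, rows: Sequence[int]) -> "DescriptorTable":
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            compound_ids=[self.compound_ids[i] for i in rows],
            values=self.values[rows].copy(),
            response=self.response[rows].copy(),
            partition_labels=(
                None if self.partition_labels is None else self.partition_labels[rows]
            ),
        )

    def to_frame(self, response_column: str = "rt_min", id_column: str = "id") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, id_column, self.compound_ids)
        df[response_column] = self.response
        if self.partition_labels is not None:
            df["partition"] = self.partition_labels
        return df


@dataclass(frozen=True)
class Partition:
    """Disjoint train/val/test row-index sets covering all rows."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        total = len(self.train_idx) + len(self.val_idx) + len(self.test_idx)
        union = sets[0] | sets[1] | sets[2]
        if len(union) != total:
            raise DatasetError("partition index sets overlap")


def _fixture_path():
    return resources.files("qsrr.data").joinpath(_FIXTURE_NAME)


def fixture_frame() -> pd.DataFrame:
    """Return the packaged compound table as a DataFrame, order preserved."""
    with resources.as_file(_fixture_path()) as p:
        return pd.read_csv(p, dtype={"name": str, "category": str, "partition": str})


def load_fixture() -> list[CompoundRecord]:
    """Load the packaged 75-compound table with its printed train/test labels."""
    df = fixture_frame()
    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        fields = ["index", "name", "rt_exp_min", "mw", "xlogp3", "hbd", "partition"]
        for f in fields:
            v = row[f]
            if (isinstance(v, float) and math.isnan(v)) or (isinstance(v, str) and not v.strip()):
                raise DatasetError(f"fixture row {i + 1}: missing value in column '{f}'")
        records.append(
            CompoundRecord(
                index=int(row["index"]),
                name=str(row["name"]),
                rt_exp=float(row["rt_exp_min"]),
                category=str(row["category"]),
                mw=float(row["mw"]),
                xlogp3=float(row["xlogp3"]),
                hbd=int(row["hbd"]),
                partition=str(row["partition"]),
            )
        )
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise DatasetError(f"duplicate compound names in fixture: {dupes}")
    return records


def load_descriptor_table(
    path: str | Path,
    response_column: str = "rt_min",
    id_column: str = "id",
) -> DescriptorTable:
    """Read a compounds x descriptors CSV with a header row.

    Column order is preserved; every descriptor cell must parse as a number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DatasetError(f"{path.name}: duplicated descriptor header(s): {dupes}")
    df = pd.read_csv(path, dtype={id_column: str} if id_column else None)
    for col in (response_column, id_column):
        if col not in df.columns:
            raise DatasetError(f"{path.name}: missing required column '{col}'")
    labels = None
    desc_cols = [c for c in df.columns if c not in (response_column, id_column, "partition")]
    if "partition" in df.columns:
        labels = df["partition"].to_numpy(dtype=object)
    numeric = df[desc_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[desc_cols].notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DatasetError(
            f"{path.name}: non-numeric descriptor cell at row {r + 1}, column '{desc_cols[c]}'"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DatasetError(
            f"{path.name}: missing descriptor value at row {r + 1}, column '{desc_cols[c]}'"
        )
    response = pd.to_numeric(df[response_column], errors="coerce")
    if response.isna().any():
        r = int(np.argwhere(response.isna().to_numpy())[0][0])
        raise DatasetError(f"{path.name}: missing/non-numeric response at row {r + 1}")
    return DescriptorTable(
        compound_ids=df[id_column].astype(str).tolist(),
        descriptor_names=desc_cols,
        values=numeric.to_numpy(dtype=float),
        response=response.to_numpy(dtype=float),
        partition_labels=labels,
    )


def write_table(
    table: DescriptorTable,
    path: str | Path,
    response_column: str = "rt_min",
    id_column: str = "id",
) -> None:
    """Write a DescriptorTable as CSV, full double precision."""
    df = table.to_frame(response_column=response_column, id_column=id_column)
    df.to_csv(path, index=False, float_format="%.17g")


def write_predictions(
    path: str | Path,
    ids: Sequence[str],
    y_exp: np.ndarray,
    y_pred: np.ndarray,
    partition: Sequence[str],
) -> pd.DataFrame:
    """Write per-compound predictions with residuals e = y_exp - y_pred."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    df = pd.DataFrame(
        {
            "id": list(ids),
            "y_exp": y_exp,
            "y_pred": y_pred,
            "residual": y_exp - y_pred,
            "partition": list(partition),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def _round_robin_order(order: np.ndarray, cycle: int = 5) -> np.ndarray:
    """Interleave a sorted ordering into `cycle` strides laid end to end."""
    return np.concatenate([order[i::cycle] for i in range(cycle)])


def make_partition(table: DescriptorTable, scheme: str, seed: int = 0) -> Partition:
    """Split rows into train/val/test index sets.

    ``fixed_80_20`` honors existing train/test labels when present; otherwise
    it assigns the first ceil(0.8 n) rows of an RT-sorted round-robin ordering
    to training.  ``stratified_70_15_15`` sorts rows by response, forms
    consecutive strata of ~7 rows and samples 70/15/15 within each stratum.
    """
    n = table.n
    empty = np.array([], dtype=int)
    if scheme == "fixed_80_20":
        labels = table.partition_labels
        if labels is not None and set(labels) <= {"train", "test"}:
            train = np.flatnonzero(labels == "train")
            test = np.flatnonzero(labels == "test")
            return Partition(train, empty, test, scheme, seed)
        order = np.argsort(table.response, kind="stable")
        rr = _round_robin_order(order, cycle=5)
        n_train = int(math.ceil(0.8 * n))
        train = np.sort(rr[:n_train])
        test = np.sort(rr[n_train:])
        return Partition(train, empty, test, scheme, seed)
    if scheme == "stratified_70_15_15":
        if n < 10:
            raise DatasetError("stratified_70_15_15 requires n >= 10")
        rng = np.random.default_rng(seed)
        order = np.argsort(table.response, kind="stable")
        strata = [order[i : i + 7] for i in range(0, n, 7)]
        n_test = int(round(0.15 * n))
        n_val = int(round(0.15 * n))
        train, val, test = [], [], []
        # Bresenham-style cumulative allocation keeps global 70/15/15 exact
        # while spreading held-out rows across the RT range.
        cum_rows = 0
        taken_val = taken_test = 0
        for stratum in strata:
            cum_rows += len(stratum)
            want_val = int(round(n_val * cum_rows / n)) - taken_val
            want_test = int(round(n_test * cum_rows / n)) - taken_test
            want_val = min(want_val, len(stratum))
            want_test = min(want_test, len(stratum) - want_val)
            perm = rng.permutation(stratum)
            val.extend(perm[:want_val])
            test.extend(perm[want_val : want_val + want_test])
            train.extend(perm[want_val + want_test :])
            taken_val += want_val
            taken_test += want_test
        return Partition(
            np.sort(np.array(train, dtype=int)),
            np.sort(np.array(val, dtype=int)),
            np.sort(np.array(test, dtype=int)),
            scheme,
            seed,
        )
    raise DatasetError(f"unknown partition scheme: {scheme!r}")


def fixture_table() -> DescriptorTable:
    """The packaged table viewed as a DescriptorTable (mw, xlogp3, hbd as columns)."""
    df = fixture_frame()
    return DescriptorTable(
        compound_ids=df["name"].tolist(),
        descriptor_names=["mw", "xlogp3", "hbd"],
        values=df[["mw", "xlogp3", "hbd"]].to_numpy(dtype=float),
        response=df["rt_exp_min"].to_numpy(dtype=float),
        partition_labels=df["partition"].to_numpy(dtype=object),
    )
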