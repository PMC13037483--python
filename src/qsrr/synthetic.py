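"""Synthetic descriptor matrices with known ground truth.

Emulates the statistical structure a GC-QSRR descriptor pool presents to the
selection/regression machinery: many columns, strong within-block
collinearity, a handful of informative descriptors, constant and
near-constant nuisance columns, and an RT response in the ~0.9-2.2 min range
of the packaged drug table.  Real molecular descriptors (RDF, Balaban J,
log P, ...) are not simulated from structures; only their correlation
geometry is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset_io import DatasetError, DescriptorTable

__all__ = ["SyntheticSpec", "SyntheticDataset", "RecoverySummary", "generate", "truth_report"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic QSRR dataset.

    ``rho`` is the within-block descriptor correlation; blocks are mutually
    independent.  Exactly one informative descriptor is placed per block so a
    |r|>0.90 collinearity pre-filter cannot delete the whole truth set.
    """

    n: int = 75
    K: int = 200
    k_true: int = 7
    block_size: int = 5
    rho: float = 0.9
    surface: str = "linear"          # or "nonlinear"
    noise_sd: float = 0.03           # minutes
    n_constant: int = 3
    n_near_constant: int = 3
    rt_range: tuple[float, float] = (0.9, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_true <= self.K):
            raise DatasetError("require 1 <= k_true <= K")
        if not (0 <= self.rho < 1):
            raise DatasetError("require 0 <= rho < 1")
        if self.noise_sd < 0:
            raise DatasetError("noise_sd must be >= 0")
        if not (self.rt_range[0] < self.rt_range[1]):
            raise DatasetError("rt_range must satisfy low < high")
        if self.surface not in ("linear", "nonlinear"):
            raise DatasetError(f"unknown surface: {self.surface!r}")


@dataclass
class SyntheticDataset:
    """Generated table plus the ground truth used to score recovery."""

    table: DescriptorTable
    true_mask: np.ndarray            # bool, length K
    true_coefficients: np.ndarray    # beta over the true columns (surface scale)
    surface: str
    interaction: tuple[int, int, float] | None   # (col_a, col_b, gamma) for nonlinear
    rescale: tuple[float, float]     # (a, b): rt = a * raw + b before noise
    noise_sd: float
    seed: int

    @property
    def true_names(self) -> list[str]:
        return [d for d, m in zip(self.table.descriptor_names, self.true_mask) if m]

    def raw_surface(self, values: np.ndarray | None = None) -> np.ndarray:
        """Recompute the noiseless surface from descriptor values (unscaled)."""
        X = self.table.values if values is None else np.asarray(values, dtype=float)
        idx = np.flatnonzero(self.true_mask)
        Xt = X[:, idx]
        if self.surface == "linear":
            return Xt @ self.true_coefficients
        raw = np.tanh(Xt) @ self.true_coefficients
        a, b, gamma = self.interaction
        return raw + gamma * X[:, a] * X[:, b]

    def noiseless_response(self) -> np.ndarray:
        a, b = self.rescale
        return a * self.raw_surface() + b


@dataclass(frozen=True)
class RecoverySummary:
    tp: int
    fp: int
    fn: int
    jaccard: float


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset: block-correlated Gaussian descriptors, RT response.

    Descriptors within a block share a latent factor, x = sqrt(rho) z_block +
    sqrt(1-rho) eps, giving exact pairwise correlation rho in expectation.
    The response is built from k_true columns (one per block), affinely
    rescaled into rt_range, then Gaussian noise is added.  Constant and
    near-constant columns are appended last.  Deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    k_core = spec.K - spec.n_constant - spec.n_near_constant
    if k_core < spec.k_true:
        raise DatasetError("K too small for k_true plus injected nuisance columns")
    n_blocks = int(np.ceil(k_core / spec.block_size))
    if spec.k_true > n_blocks:
        raise DatasetError(
            f"k_true={spec.k_true} exceeds the number of blocks ({n_blocks})"
        )

    X = np.empty((spec.n, k_core))
    block_of = np.empty(k_core, dtype=int)
    for b in range(n_blocks):
        lo = b * spec.block_size
        hi = min(lo + spec.block_size, k_core)
        z = rng.standard_normal((spec.n, 1))
        eps = rng.standard_normal((spec.n, hi - lo))
        X[:, lo:hi] = np.sqrt(spec.rho) * z + np.sqrt(1.0 - spec.rho) * eps
        block_of[lo:hi] = b

    # one informative column per distinct block
    true_blocks = rng.choice(n_blocks, size=spec.k_true, replace=False)
    true_idx = np.array(
        [rng.choice(np.flatnonzero(block_of == b)) for b in sorted(true_blocks)]
    )
    beta = rng.uniform(0.5, 1.5, size=spec.k_true) * rng.choice([-1.0, 1.0], spec.k_true)

    interaction = None
    if spec.surface == "linear":
        raw = X[:, true_idx] @ beta
    else:
        raw = np.tanh(X[:, true_idx]) @ beta
        a_col, b_col = rng.choice(true_idx, size=2, replace=False)
        gamma = float(rng.uniform(0.3, 0.8) * rng.choice([-1.0, 1.0]))
        raw = raw + gamma * X[:, a_col] * X[:, b_col]
        interaction = (int(a_col), int(b_col), gamma)

    lo, hi = spec.rt_range
    span = raw.max() - raw.min()
    if span <= 0:
        a = 0.0
        b = 0.5 * (lo + hi)
    else:
        a = (hi - lo) / span
        b = lo - a * raw.min()
    y = a * raw + b
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)

    # nuisance columns appended last, never informative
    cols = [X]
    names = [f"X{j + 1:04d}" for j in range(k_core)]
    for c in range(spec.n_constant):
        cols.append(np.full((spec.n, 1), float(rng.uniform(-2, 2))))
        names.append(f"const_{c + 1}")
    n_jitter = max(1, int(np.floor(0.04 * spec.n)))
    for c in range(spec.n_near_constant):
        base = float(rng.uniform(-2, 2))
        col = np.full(spec.n, base)
        where = rng.choice(spec.n, size=n_jitter, replace=False)
        col[where] = base + rng.normal(0.0, 0.05, size=n_jitter)
        cols.append(col[:, None])
        names.append(f"nearconst_{c + 1}")

    values = np.hstack(cols)
    true_mask = np.zeros(spec.K, dtype=bool)
    true_mask[true_idx] = True

    table = DescriptorTable(
        compound_ids=[f"S{i + 1:03d}" for i in range(spec.n)],
        descriptor_names=names,
        values=values,
        response=y,
    )
    return SyntheticDataset(
        table=table,
        true_mask=true_mask,
        true_coefficients=beta,
        surface=spec.surface,
        interaction=interaction,
        rescale=(a, b),
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )


def truth_report(ds: SyntheticDataset, selected: Sequence[str]) -> RecoverySummary:
    """Score a selected descriptor-name set against the generating truth."""
    known = set(ds.table.descriptor_names)
    unknown = sorted(set(selected) - known)
    if unknown:
        raise DatasetError(f"unknown descriptor names: {unknown}")
    sel = set(selected)
    truth = set(ds.true_names)
    tp = len(sel & truth)
    fp = len(sel - truth)
    fn = len(truth - sel)
    union = len(sel | truth)
    jacc = tp / union if union else 0.0
    return RecoverySummary(tp=tp, fp=fp, fn=fn, jaccard=jacc)
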