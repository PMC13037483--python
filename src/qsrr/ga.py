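"""Genetic-algorithm wrapper selection of descriptors.

Chromosomes are binary inclusion masks over the pretreated descriptor pool.
Fitness is cross-validated predictive power minus a parsimony penalty,
Q2_cv - alpha * k/K, where Q2_cv = 1 - PRESS/TSS from an inner k-fold CV of
the configured estimator (PLS or kernel PLS) restricted to the masked
columns.  Evolution uses tournament selection (size 2), single-point
crossover, per-gene mutation and elitism; runs stop on a generation limit
or when the best fitness stalls.  Stability across independent runs is
summarized as per-descriptor selection frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .latent_models import _pls_nipals, fit_kpls

__all__ = [
    "GAConfig",
    "GARunResult",
    "ConsensusReport",
    "fitness",
    "crossover",
    "mutate",
    "run_ga",
    "consensus",
    "ga_select",
]

_NEG_INF = -np.inf


class GAError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 30
    p_crossover: float = 0.5
    p_mutation_per_gene: float = 0.01
    max_generations: int = 1000
    stall_patience: int = 100       # generations
    stall_tol: float = 0.001        # fitness units
    n_runs: int = 20
    alpha: float = 0.05             # parsimony weight
    inner_cv: int = 5               # fold count; n for leave-one-out
    estimator: str = "pls"          # or "kpls"
    n_lv: int = 4
    sigma: float | None = None      # kpls only; None -> median-distance heuristic
    elitism: int = 1
    init_p: float = 0.1             # per-bit inclusion probability at init
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation_per_gene <= 1):
            raise GAError("probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise GAError("pop_size must be >= 2")
        if self.alpha < 0:
            raise GAError("alpha must be >= 0")
        if self.estimator not in ("pls", "kpls"):
            raise GAError(f"unknown estimator: {self.estimator!r}")


@dataclass
class GARunResult:
    best_mask: np.ndarray
    best_fitness: float
    fitness_trace: list[float]      # per-generation best (elitist, non-decreasing)
    generations_run: int
    run_seed: int
    fold_seed: int = 0              # inner-CV fold assignment used throughout the run


@dataclass
class ConsensusReport:
    selection_frequency: pd.DataFrame   # columns: descriptor, frequency, in_final
    final_mask: np.ndarray
    final_cv_fitness: float
    per_run: pd.DataFrame               # run, seed, fitness, n_selected, generations


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def _cv_q2(Xm: np.ndarray, y: np.ndarray, config: GAConfig, fold_order: np.ndarray) -> float:
    """Inner-CV Q2 of the configured estimator on the masked columns.

    Per fold, the training rows are autoscaled (zero-sd guard), the model is
    fit and the held-out rows predicted.  Q2 = 1 - PRESS/TSS about the grand
    mean of y.
    """
    n = Xm.shape[0]
    k_folds = min(config.inner_cv, n)
    folds = np.array_split(fold_order, k_folds)
    press = 0.0
    for fold in folds:
        if fold.size == 0:
            continue
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = Xm[mask], y[mask]
        Xte = Xm[fold]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd < 1e-12] = 1.0
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (Xte - mu) / sd
        ym = ytr.mean()
        yc = ytr - ym
        n_lv = min(config.n_lv, Xtr.shape[1], Xtr.shape[0] - 1)
        if config.estimator == "pls":
            _, _, _, _, coef = _pls_nipals(Xtr_s, yc, n_lv)
            pred = ym + Xte_s @ coef
        else:
            sigma = config.sigma
            if sigma is None:
                from scipy.spatial.distance import pdist

                d = pdist(Xtr_s)
                sigma = float(np.median(d))
                if sigma <= 0:
                    raise GAError("degenerate fold distances")
            m = fit_kpls(Xtr, ytr, sigma, n_lv)
            pred = m.predict(Xte)
        press += float(np.sum((y[fold] - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise GAError("response has zero variance")
    return 1.0 - press / tss


def fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    fold_seed: int = 0,
) -> float:
    """Penalized fitness Q2_cv - alpha * k_selected / K (higher is better).

    Estimator failure on a degenerate mask yields -inf so the chromosome is
    culled by selection.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return _NEG_INF
    k = int(mask.sum())
    fold_order = np.random.default_rng(fold_seed).permutation(X.shape[0])
    try:
        q2 = _cv_q2(X[:, mask], y, config, fold_order)
    except (ValueError, np.linalg.LinAlgError):
        return _NEG_INF
    return q2 - config.alpha * k / mask.size


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
    p_crossover: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover with probability p; empty children repaired."""
    a = np.asarray(parent_a, dtype=bool)
    b = np.asarray(parent_b, dtype=bool)
    if a.shape != b.shape:
        raise GAError("parents must have equal length")
    if rng.random() < p_crossover and a.size > 1:
        cut = int(rng.integers(1, a.size))
        child_a = np.concatenate([a[:cut], b[cut:]])
        child_b = np.concatenate([b[:cut], a[cut:]])
    else:
        child_a, child_b = a.copy(), b.copy()
    return _repair(child_a, rng), _repair(child_b, rng)


def mutate(
    chromosome: np.ndarray,
    rng: np.random.Generator,
    p_gene: float = 0.01,
) -> np.ndarray:
    """Flip each bit independently with probability p_gene; repair if empty."""
    mask = np.asarray(chromosome, dtype=bool)
    flips = rng.random(mask.size) < p_gene
    return _repair(mask ^ flips, rng)


def run_ga(
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    run_seed: int = 0,
) -> GARunResult:
    """One GA run: seeded init, tournament/crossover/mutation, elitist trace.

    Stops at max_generations or when the best fitness has improved by less
    than stall_tol for stall_patience consecutive generations.  Fully
    deterministic given run_seed; fitness evaluations are memoized per mask
    within the run (the fold assignment is fixed per run).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = X.shape[1]
    if K < 2:
        raise GAError("need at least 2 descriptors")
    rng = np.random.default_rng(run_seed)
    fold_seed = int(rng.integers(2**31))
    memo: dict[bytes, float] = {}

    def fit_of(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in memo:
            memo[key] = fitness(mask, X, y, config, fold_seed=fold_seed)
        return memo[key]

    pop = [
        _repair(rng.random(K) < config.init_p, rng) for _ in range(config.pop_size)
    ]
    best_fit = _NEG_INF
    best_mask = pop[0].copy()
    trace: list[float] = []
    stall = 0
    generations = 0
    for gen in range(config.max_generations):
        generations = gen + 1
        fits = np.array([fit_of(m) for m in pop])
        order = np.argsort(-fits, kind="stable")
        gen_best = fits[order[0]]
        if gen_best > best_fit + config.stall_tol:
            stall = 0
        else:
            stall += 1
        if gen_best > best_fit:
            best_fit = float(gen_best)
            best_mask = pop[order[0]].copy()
        trace.append(best_fit)
        if stall >= config.stall_patience:
            break
        # next generation: elites plus tournament offspring
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.pop_size:
            def pick() -> np.ndarray:
                i, j = rng.integers(config.pop_size, size=2)
                return pop[i] if fits[i] >= fits[j] else pop[j]

            c1, c2 = crossover(pick(), pick(), rng, config.p_crossover)
            new_pop.append(mutate(c1, rng, config.p_mutation_per_gene))
            if len(new_pop) < config.pop_size:
                new_pop.append(mutate(c2, rng, config.p_mutation_per_gene))
        pop = new_pop
    return GARunResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        fitness_trace=trace,
        generations_run=generations,
        run_seed=run_seed,
        fold_seed=fold_seed,
    )


def consensus(
    runs: list[GARunResult],
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    descriptor_names: list[str] | None = None,
    fresh_fold_seed: int = 10_007,
) -> ConsensusReport:
    """Aggregate independent runs into selection frequencies and a final mask.

    The final mask is the run-best mask with the highest re-evaluated CV
    fitness under a fresh fold seed; ties break toward the mask whose
    members have the higher mean selection frequency, then the smaller mask.
    """
    if not runs:
        raise GAError("consensus requires at least one run")
    K = runs[0].best_mask.size
    names = descriptor_names or [f"X{j + 1:04d}" for j in range(K)]
    freq = np.mean([r.best_mask for r in runs], axis=0)

    unique: dict[bytes, np.ndarray] = {}
    for r in runs:
        unique.setdefault(np.packbits(r.best_mask).tobytes(), r.best_mask)
    scored = []
    for mask in unique.values():
        f = fitness(mask, X, y, config, fold_seed=fresh_fold_seed)
        mean_freq = float(freq[mask].mean())
        scored.append((f, mean_freq, -int(mask.sum()), mask))
    scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    final_fit, _, _, final_mask = scored[0]

    per_run = pd.DataFrame(
        {
            "run": range(len(runs)),
            "seed": [r.run_seed for r in runs],
            "best_fitness": [r.best_fitness for r in runs],
            "n_selected": [int(r.best_mask.sum()) for r in runs],
            "generations": [r.generations_run for r in runs],
        }
    )
    table = pd.DataFrame(
        {
            "descriptor": names,
            "frequency": freq,
            "in_final": final_mask,
        }
    )
    return ConsensusReport(
        selection_frequency=table,
        final_mask=final_mask,
        final_cv_fitness=float(final_fit),
        per_run=per_run,
    )


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    descriptor_names: list[str] | None = None,
) -> ConsensusReport:
    """Run config.n_runs independent GA searches and build the consensus."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_runs)]
    runs = [run_ga(X, y, config, run_seed=s) for s in seeds]
    fresh = int(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31))
    return consensus(runs, X, y, config, descriptor_names, fresh_fold_seed=fresh)
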