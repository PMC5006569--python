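"""Adaptive genetic algorithm for ensemble weight optimization.

The final classifier is the weighted average F(x) = sum_i w_i f_i(x) of base
learner probabilities, with the weight vector living on the probability
simplex (w_i >= 0, sum w_i = 1) so that F(x) stays in [0, 1]. The weights are
found by a real-coded genetic algorithm whose fitness is the AUC of the
ensemble on a held-out validation fold.

GA design: roulette-wheel selection, uniform crossover, per-gene uniform
redraw mutation, one-elite preservation. Crossover and mutation probabilities
adapt to population fitness in the classic scheme: chromosomes at or above
the average fitness get rates that shrink linearly to zero as their fitness
approaches the population maximum, below-average chromosomes get the full
constant rates. The initial population contains the N one-hot corner vectors
and the uniform vector alongside random chromosomes, so with elitism the
final fitness can never fall below the best single base learner.

Full-size defaults are population 1000 / 500 generations; validation scores
are computed once and cached, so a generation only recombines weight vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import ParameterError, ValidationError


@dataclass(frozen=True)
class GAConfig:
    """Adaptive-GA settings; defaults are the full-size run."""

    population_size: int = 1000
    generations: int = 500
    k1: float = 1.0   # crossover scale, above-average chromosomes
    k2: float = 0.5   # mutation scale, above-average chromosomes
    k3: float = 1.0   # crossover rate, below-average chromosomes
    k4: float = 0.5   # mutation rate, below-average chromosomes
    elite_count: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if self.elite_count < 0:
            raise ParameterError("elite_count must be >= 0")


# a small config for desk-scale runs and tests
REDUCED_GA = dict(population_size=50, generations=30)


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Project nonnegative genes onto the simplex; all-zero maps to uniform."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValidationError("weight genes must be nonnegative")
    total = raw.sum()
    if total == 0:
        return np.full(raw.shape, 1.0 / raw.size)
    return raw / total


def ensemble_score(weights: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """F(x) = sum_i w_i f_i(x) per instance."""
    weights = np.asarray(weights, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or weights.shape[0] != scores.shape[1]:
        raise ValidationError(
            f"weight length {weights.shape[0]} != {scores.shape[1]} learners"
        )
    return scores @ weights


def _auc_columns(ensemble: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-statistic AUC of each column (ties count 1/2)."""
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("validation fold must contain both classes")
    ranks = rankdata(ensemble, axis=0)
    pos_rank_sum = ranks[pos].sum(axis=0)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def ga_fitness(
    weights: np.ndarray, val_scores: np.ndarray, val_labels: np.ndarray
) -> float:
    """Validation AUC of the weighted ensemble for one weight vector."""
    f = ensemble_score(np.asarray(weights), val_scores)
    return float(_auc_columns(f[:, None], val_labels)[0])


def adaptive_rates(
    f_max: float, f_avg: float, f_cross: float, f_mut: float, cfg: GAConfig
) -> tuple[float, float]:
    """Fitness-adaptive crossover and mutation probabilities.

    Above-average chromosomes get k1*(f_max-f)/(f_max-f_avg) (resp. k2*...),
    below-average ones the constants k3 (resp. k4); a fully converged
    population (f_max == f_avg) gets (k1, k2). Results are clipped to [0,1].
    """
    if f_avg > f_max:
        raise ValidationError("f_avg cannot exceed f_max")
    if f_max == f_avg:
        return cfg.k1, cfg.k2
    spread = f_max - f_avg
    p_c = cfg.k1 * (f_max - f_cross) / spread if f_cross >= f_avg else cfg.k3
    p_m = cfg.k2 * (f_max - f_mut) / spread if f_mut >= f_avg else cfg.k4
    return float(np.clip(p_c, 0.0, 1.0)), float(np.clip(p_m, 0.0, 1.0))


@dataclass
class GAResult:
    weights: np.ndarray          # normalized best-ever weight vector
    fitness: float               # its validation AUC
    trace: np.ndarray            # best-ever fitness per generation

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)


def _population_fitness(pop: np.ndarray, val_scores, val_labels) -> np.ndarray:
    normed = pop / np.where(pop.sum(axis=1, keepdims=True) == 0, 1.0,
                            pop.sum(axis=1, keepdims=True))
    zero = pop.sum(axis=1) == 0
    if zero.any():
        normed[zero] = 1.0 / pop.shape[1]
    return _auc_columns(val_scores @ normed.T, val_labels)


def ga_optimize(
    val_scores: np.ndarray,
    val_labels: np.ndarray,
    cfg: GAConfig = GAConfig(),
) -> GAResult:
    """Search the simplex for weights maximizing validation AUC.

    Returns the best-ever chromosome's normalized weights; the best-ever
    fitness trace is non-decreasing by construction (elitism on a cached
    score matrix).
    """
    val_scores = np.asarray(val_scores, dtype=float)
    val_labels = np.asarray(val_labels)
    if val_scores.ndim != 2 or val_scores.shape[1] == 0:
        raise ValidationError("score matrix must be (n_instances x N>=1)")
    n_weights = val_scores.shape[1]
    if n_weights == 1:
        fit = ga_fitness(np.ones(1), val_scores, val_labels)
        return GAResult(np.ones(1), fit, np.full(cfg.generations, fit))

    rng = np.random.default_rng(cfg.rng_seed)
    P = cfg.population_size
    pop = rng.uniform(size=(P, n_weights))
    # seed canonical candidates: one-hot corners and the uniform vector
    for i in range(min(n_weights, P)):
        pop[i] = 0.0
        pop[i, i] = 1.0
    if P > n_weights:
        pop[n_weights] = 1.0 / n_weights

    best_w = None
    best_f = -np.inf
    trace = np.empty(cfg.generations)

    for gen in range(cfg.generations):
        fitness = _population_fitness(pop, val_scores, val_labels)
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_f:
            best_f = float(fitness[gen_best])
            best_w = pop[gen_best].copy()
        trace[gen] = best_f
        if gen == cfg.generations - 1:
            break

        f_max = float(fitness.max())
        f_avg = float(fitness.mean())
        total = fitness.sum()
        sel_p = fitness / total if total > 0 else np.full(P, 1.0 / P)

        children: list[np.ndarray] = [best_w.copy() for _ in range(cfg.elite_count)]
        while len(children) < P:
            i, j = rng.choice(P, size=2, p=sel_p)
            a, b = pop[i].copy(), pop[j].copy()
            f_cross = max(float(fitness[i]), float(fitness[j]))
            p_c, _ = adaptive_rates(f_max, f_avg, f_cross, f_cross, cfg)
            if rng.uniform() < p_c:
                mask = rng.uniform(size=n_weights) < 0.5
                a[mask], b[mask] = b[mask], a[mask].copy()
            for child, f_parent in ((a, fitness[i]), (b, fitness[j])):
                _, p_m = adaptive_rates(f_max, f_avg, f_parent, float(f_parent), cfg)
                mut = rng.uniform(size=n_weights) < p_m
                if mut.any():
                    child[mut] = rng.uniform(size=int(mut.sum()))
                if len(children) < P:
                    children.append(child)
        pop = np.vstack(children)

    return GAResult(normalize_weights(best_w), best_f, trace)


def grid_search_weights(
    val_scores: np.ndarray, val_labels: np.ndarray, step: float = 0.05
) -> GAResult:
    """Exhaustive simplex-grid oracle (small N only); independent of the GA."""
    val_scores = np.asarray(val_scores, dtype=float)
    n = val_scores.shape[1]
    ticks = int(round(1.0 / step))

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for rest in compositions(total - head, parts - 1):
                yield (head, *rest)

    best_w, best_f = None, -np.inf
    for comp in compositions(ticks, n):
        w = np.array(comp, dtype=float) / ticks
        f = ga_fitness(w, val_scores, val_labels)
        if f > best_f:
            best_f, best_w = f, w
    return GAResult(best_w, float(best_f), np.array([best_f]))
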