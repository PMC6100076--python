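"""Two-stage descriptor-subset search: genetic algorithm then recursive
feature elimination.

The fitness of a candidate subset is the k-fold cross-validated RMSE of an
epsilon-SVR trained on that subset (minimised).  The GA explores
membership bitmasks with tournament selection, uniform crossover, per-bit
mutation and elitism; RFE then prunes the winner one descriptor at a
time, discarding at each round the descriptor whose removal least degrades
(or most improves) the fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .svr_engine import MemberSVR, cv_rmse

__all__ = ["SelectionResult", "GeneticDescriptorSelector", "RecursiveEliminator", "rfe"]


@dataclass
class SelectionResult:
    """Outcome of a subset search.

    ``fitness_trace`` holds per-generation (best_so_far, mean) fitness for
    the GA stage; ``elimination_order`` lists descriptors in the order RFE
    removed them with the fitness delta each removal caused (positive
    delta = removal hurt).
    """

    chosen: list[str]
    fitness_trace: list[tuple[float, float]] = field(default_factory=list)
    elimination_order: list[tuple[str, float]] = field(default_factory=list)


def _default_fitness_model() -> MemberSVR:
    # mid-grid cost with a dimension-scaled kernel width; tube matches the
    # typical response noise scale
    return MemberSVR(mode="epsilon", C=32.0, gamma="scale", epsilon=0.1)


class _FitnessCache:
    """Memoised subset fitness: same subset + folds + seed -> same value."""

    def __init__(self, X: pd.DataFrame, y: np.ndarray, folds: int, seed: int):
        self.X = X
        self.y = y
        self.folds = folds
        self.seed = seed
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            model = _default_fitness_model()
            model.descriptor_subset = sorted(subset)
            self._cache[key] = cv_rmse(
                self.X, self.y, model, folds=self.folds, seed=self.seed
            )
        return self._cache[key]


class GeneticDescriptorSelector(BaseEstimator):
    """Genetic-algorithm descriptor-subset search.

    Parameters
    ----------
    population : int
        Number of candidate subsets per generation (>= 2).
    generations : int
        Number of evolution rounds; 0 returns the best of the random
        initial population.
    subset_size_range : (int, int)
        Inclusive bounds on subset cardinality, enforced by random
        add/drop repair after crossover and mutation.
    mutation_rate : float or None
        Per-bit flip probability; None means 1/n_descriptors.
    folds : int
        Cross-validation folds of the fitness evaluation.
    seed : int
        Seeds population initialisation, tournaments, crossover, mutation
        and the CV folds; identical seeds reproduce identical searches.
    """

    def __init__(
        self,
        population: int = 30,
        generations: int = 50,
        subset_size_range: tuple[int, int] = (3, 7),
        mutation_rate: float | None = None,
        tournament_size: int = 2,
        elitism: int = 1,
        folds: int = 10,
        seed: int = 0,
    ):
        self.population = population
        self.generations = generations
        self.subset_size_range = subset_size_range
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.elitism = elitism
        self.folds = folds
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "GeneticDescriptorSelector":
        if self.population < 2:
            raise ValueError("population must be >= 2")
        names = [str(c) for c in X.columns]
        lo, hi = self.subset_size_range
        if hi > len(names):
            hi = len(names)
        lo = max(1, min(lo, hi))
        yv = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        fitness = _FitnessCache(X, yv, self.folds, self.seed)
        p_mut = self.mutation_rate if self.mutation_rate is not None else 1.0 / len(names)

        def repair(mask: np.ndarray) -> np.ndarray:
            mask = mask.copy()
            size = int(mask.sum())
            while size < lo:
                off = np.flatnonzero(~mask)
                mask[rng.choice(off)] = True
                size += 1
            while size > hi:
                on = np.flatnonzero(mask)
                mask[rng.choice(on)] = False
                size -= 1
            return mask

        def random_mask() -> np.ndarray:
            size = int(rng.integers(lo, hi + 1))
            mask = np.zeros(len(names), dtype=bool)
            mask[rng.choice(len(names), size=size, replace=False)] = True
            return mask

        def mask_fitness(mask: np.ndarray) -> float:
            return fitness([names[i] for i in np.flatnonzero(mask)])

        pop = [random_mask() for _ in range(self.population)]
        scores = np.array([mask_fitness(m) for m in pop])
        trace: list[tuple[float, float]] = []
        best_idx = int(np.argmin(scores))
        best_mask, best_score = pop[best_idx].copy(), float(scores[best_idx])
        trace.append((best_score, float(scores.mean())))

        for _ in range(self.generations):
            new_pop: list[np.ndarray] = []
            # elitism: carry the best individuals unchanged
            elite_order = np.argsort(scores, kind="stable")[: self.elitism]
            for e in elite_order:
                new_pop.append(pop[int(e)].copy())
            while len(new_pop) < self.population:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(0, self.population, size=self.tournament_size)
                    winner = min(contenders, key=lambda i: (scores[i], i))
                    parents.append(pop[int(winner)])
                cross = rng.random(len(names)) < 0.5
                child = np.where(cross, parents[0], parents[1])
                flip = rng.random(len(names)) < p_mut
                child = np.logical_xor(child, flip)
                new_pop.append(repair(child))
            pop = new_pop
            scores = np.array([mask_fitness(m) for m in pop])
            gen_best = int(np.argmin(scores))
            if scores[gen_best] < best_score:
                best_score = float(scores[gen_best])
                best_mask = pop[gen_best].copy()
            trace.append((best_score, float(scores.mean())))

        chosen = [names[i] for i in np.flatnonzero(best_mask)]
        self.result_ = SelectionResult(chosen=chosen, fitness_trace=trace)
        self.chosen_ = chosen
        self.best_fitness_ = best_score
        return self


class RecursiveEliminator(BaseEstimator):
    """Backward elimination ranked by contribution to the fitness.

    A descriptor's contribution is the fitness increase its removal would
    cause; each round removes the least-contributing descriptor (the one
    whose removal yields the lowest CV RMSE) until ``floor_size`` remain.
    Ties resolve to the earlier column, making runs reproducible.
    """

    def __init__(self, floor_size: int = 3, folds: int = 10, seed: int = 0):
        self.floor_size = floor_size
        self.folds = folds
        self.seed = seed

    def fit(
        self,
        X: pd.DataFrame,
        y: Sequence[float],
        start_subset: Sequence[str] | None = None,
    ) -> "RecursiveEliminator":
        if self.floor_size < 1:
            raise ValueError("floor_size must be >= 1")
        names = [str(c) for c in (start_subset if start_subset is not None else X.columns)]
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"start_subset names not in table: {missing}")
        yv = np.asarray(y, dtype=float).ravel()
        fitness = _FitnessCache(X, yv, self.folds, self.seed)

        current = list(names)
        elimination: list[tuple[str, float]] = []
        self.path_: list[list[str]] = [list(current)]
        while len(current) > self.floor_size:
            base = fitness(current)
            candidates = []
            for idx, name in enumerate(current):
                reduced = [n for n in current if n != name]
                candidates.append((fitness(reduced), idx, name))
            best_fit, _, victim = min(candidates)
            elimination.append((victim, best_fit - base))
            current = [n for n in current if n != victim]
            self.path_.append(list(current))

        self.result_ = SelectionResult(chosen=list(current), elimination_order=elimination)
        self.chosen_ = list(current)
        return self


def rfe(
    X: pd.DataFrame,
    y: Sequence[float],
    start_subset: Sequence[str] | None = None,
    floor_size: int = 3,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Functional wrapper over :class:`RecursiveEliminator`."""
    est = RecursiveEliminator(floor_size=floor_size, folds=folds, seed=seed)
    est.fit(X, y, start_subset=start_subset)
    return est.result_


def ga_subset_search(
    X: pd.DataFrame,
    y: Sequence[float],
    population: int = 30,
    generations: int = 50,
    subset_size_range: tuple[int, int] = (3, 7),
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Functional wrapper over :class:`GeneticDescriptorSelector`."""
    est = GeneticDescriptorSelector(
        population=population,
        generations=generations,
        subset_size_range=subset_size_range,
        folds=folds,
        seed=seed,
    )
    est.fit(X, y)
    return est.result_
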