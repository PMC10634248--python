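"""Genetic-algorithm search for parsimonious LDA marker panels.

Marker subsets are binary chromosomes (bit = marker included).  Fitness is
the mean cross-validated LDA accuracy minus a parsimony penalty per
included marker, so among equally accurate subsets the smaller always
wins.  Following the study protocol, the search is run several times
(default 4) and every distinct subset present in the final generations is
re-evaluated with 30 runs of independent 2-fold cross-validation; the
re-evaluation uses a seed stream independent of the search.  Solutions
are ranked by re-evaluated accuracy (ties: smaller subset, then marker
ids), producing a report of accuracy / sensitivity / specificity per
solution.

The GA hyperparameters (population 100, 50 generations, tournament size
3, uniform crossover 0.8, per-bit mutation 1/p, elitism 1, penalty 0.005
per marker) are ordinary textbook defaults and all configurable; results
should not hinge on their exact values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from immunoprofiles.discriminant import cv_evaluate

__all__ = ["GAConfig", "GASolution", "fitness", "run_ga", "select_solutions"]


@dataclass
class GAConfig:
    population_size: int = 100
    n_generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob_per_bit: float | None = None  # default 1/p
    tournament_size: int = 3
    elitism: int = 1
    parsimony_lambda: float = 0.005
    n_runs: int = 4
    search_repeats: int = 5  # CV repeats during search
    reeval_repeats: int = 30
    reeval_folds: int = 2
    max_subset_size: int | None = None
    seed: int = 0

    def validate(self, p: int) -> None:
        if self.population_size < 1 or self.n_generations < 1 or self.n_runs < 1:
            raise ValueError("sizes must be >= 1")
        for name in ("crossover_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.mutation_prob_per_bit is not None and not (
            0.0 <= self.mutation_prob_per_bit <= 1.0
        ):
            raise ValueError("mutation_prob_per_bit must lie in [0,1]")
        if self.tournament_size < 1 or self.elitism < 0:
            raise ValueError("invalid tournament/elitism")
        if p < 2:
            raise ValueError("need at least 2 candidate markers")


@dataclass
class GASolution:
    marker_ids: tuple[str, ...]
    fitness: float  # search-time fitness
    accuracy: float  # re-evaluated
    sensitivity: float
    specificity: float
    rank: int


def fitness(
    subset: np.ndarray | tuple[int, ...],
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
) -> float:
    """Search-time fitness: mean CV accuracy minus parsimony penalty.

    ``subset`` is a boolean mask or an index tuple over the columns of X.
    The CV partitions are seeded identically for every subset so fitness
    values are comparable.
    """
    cols = np.asarray(subset)
    if cols.dtype == bool:
        cols = np.flatnonzero(cols)
    if cols.size == 0:
        raise ValueError("empty marker subset")
    rep = cv_evaluate(
        X[:, cols],
        y,
        n_repeats=config.search_repeats,
        n_folds=config.reeval_folds,
        seed=config.seed,
    )
    return rep.accuracy - config.parsimony_lambda * cols.size


def _repair(chrom: np.ndarray, rng: np.random.Generator, cap: int | None) -> None:
    """In place: never empty; enforce the optional subset-size cap."""
    if not chrom.any():
        chrom[rng.integers(len(chrom))] = True
    if cap is not None and chrom.sum() > cap:
        on = np.flatnonzero(chrom)
        off = rng.choice(on, size=int(chrom.sum()) - cap, replace=False)
        chrom[off] = False
        if not chrom.any():  # cap >= 1 guaranteed by validate
            chrom[rng.integers(len(chrom))] = True


def _single_run(
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    cache: dict[tuple[int, ...], float],
) -> list[tuple[np.ndarray, float]]:
    n, p = X.shape
    mut = config.mutation_prob_per_bit or 1.0 / p
    cap = config.max_subset_size

    def evaluate(chrom: np.ndarray) -> float:
        key = tuple(np.flatnonzero(chrom))
        if key not in cache:
            cache[key] = fitness(chrom, X, y, config)
        return cache[key]

    pop = rng.random((config.population_size, p)) < 0.5
    for chrom in pop:
        _repair(chrom, rng, cap)
    fits = np.array([evaluate(c) for c in pop])

    for _ in range(config.n_generations):
        elite_idx = np.argsort(-fits, kind="stable")[: config.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            a, b = parents
            if rng.random() < config.crossover_prob:
                swap = rng.random(p) < 0.5
                a[swap], b[swap] = b[swap].copy(), a[swap].copy()
            for child in (a, b):
                flip = rng.random(p) < mut
                child[flip] = ~child[flip]
                _repair(child, rng, cap)
                if len(children) < config.population_size:
                    children.append(child)
        pop = np.array(children)
        fits = np.array([evaluate(c) for c in pop])

    seen: dict[tuple[int, ...], float] = {}
    for chrom, f in zip(pop, fits):
        seen.setdefault(tuple(np.flatnonzero(chrom)), f)
    return [(np.asarray(k, dtype=int), f) for k, f in seen.items()]


def run_ga(
    X: np.ndarray, y: np.ndarray, config: GAConfig | None = None
) -> list[list[tuple[np.ndarray, float]]]:
    """Run the GA ``config.n_runs`` times; return each run's de-duplicated
    final generation as (column-index array, fitness) pairs."""
    cfg = config or GAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    cfg.validate(X.shape[1])
    cache: dict[tuple[int, ...], float] = {}
    out = []
    for r in range(cfg.n_runs):
        rng = np.random.default_rng([cfg.seed, r])
        out.append(_single_run(X, y, cfg, rng, cache))
    return out


def select_solutions(
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig | None = None,
    marker_ids: tuple[str, ...] | None = None,
) -> list[GASolution]:
    """Full protocol: multi-run GA, pooled final generations, 30x2-fold
    re-evaluation with a fresh seed stream, ranked solution report."""
    cfg = config or GAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    ids = (
        tuple(marker_ids)
        if marker_ids is not None
        else tuple(f"m{j}" for j in range(X.shape[1]))
    )
    finals = run_ga(X, y, cfg)
    pooled: dict[tuple[int, ...], float] = {}
    for run_pop in finals:
        for cols, f in run_pop:
            pooled.setdefault(tuple(cols.tolist()), f)

    solutions = []
    # seed stream for re-evaluation, independent of the search seed usage
    for i, (cols, search_fit) in enumerate(sorted(pooled.items())):
        rep = cv_evaluate(
            X[:, list(cols)],
            y,
            n_repeats=cfg.reeval_repeats,
            n_folds=cfg.reeval_folds,
            seed=int(np.random.default_rng([cfg.seed, 10_000 + i]).integers(2**31)),
        )
        solutions.append(
            GASolution(
                marker_ids=tuple(ids[j] for j in cols),
                fitness=search_fit,
                accuracy=rep.accuracy,
                sensitivity=rep.sensitivity,
                specificity=rep.specificity,
                rank=0,
            )
        )
    solutions.sort(key=lambda s: (-s.accuracy, len(s.marker_ids), s.marker_ids))
    for r, s in enumerate(solutions, start=1):
        s.rank = r
    return solutions


def solutions_to_dataframe(solutions: list[GASolution]) -> pd.DataFrame:
    """Ranked-solution report mirroring the study's GA results table."""
    return pd.DataFrame(
        {
            "rank": [s.rank for s in solutions],
            "markers": [";".join(s.marker_ids) for s in solutions],
            "n_markers": [len(s.marker_ids) for s in solutions],
            "accuracy": [s.accuracy for s in solutions],
            "sensitivity": [s.sensitivity for s in solutions],
            "specificity": [s.specificity for s in solutions],
        }
    )
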