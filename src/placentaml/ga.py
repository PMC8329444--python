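"""Genetic-algorithm feature selection guided by the training F_1/2 score.

Individuals are ordered sets of six distinct descriptor names. Each is scored
by fitting the chosen classifier on the training rows restricted to those
descriptors, predicting the same rows, and taking the F_1/2 of the resulting
confusion (undefined scores count as 0). The population of 1,000 evolves for
199 iterations:

1. the best-scored individual (the optimal individual) is recorded;
2. 500 children are formed by crossing random pairs from the top half — the
   first three features of one parent and the complementary last three of
   the other, duplicates replaced by random pool features;
3. each child mutates with probability 0.2: it becomes a copy of the optimal
   individual with two random positions overwritten by random pool features;
4. the children unconditionally replace the bottom half, one third of the
   remaining top half (never the optimal individual) is replaced by fresh
   random individuals, and every 50 iterations the whole population is
   regenerated keeping only the top 10.

Elitism makes the best-so-far fitness non-decreasing across iterations and
restarts. Fitness evaluations are memoized on the feature *set* (order inside
an individual only matters for crossover).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.preprocessing import StandardScaler

from .metrics import NEGATIVE_LABEL, POSITIVE_LABEL, confusion, f_beta
from .modeling import ClassifierSpec, _backend

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    """An ordered set of distinct candidate features, optionally scored."""

    features: tuple[str, ...]
    fitness: Optional[float] = None

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features in individual: {self.features}")

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.features))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings; defaults are the full-scale run."""

    population_size: int = 1000
    n_offspring: Optional[int] = None  # defaults to population_size // 2
    n_iterations: int = 199
    mutation_prob: float = 0.2
    restart_period: int = 50
    restart_elite: int = 10
    diversity_fraction: float = 1.0 / 3.0
    individual_size: int = 6
    mutation_strategy: str = "best_copy"  # or "child"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ConfigurationError("population_size must be a positive even number")
        offspring = self.n_offspring
        if offspring is None:
            object.__setattr__(self, "n_offspring", self.population_size // 2)
        elif offspring != self.population_size // 2:
            raise ConfigurationError(
                "n_offspring must equal population_size / 2 "
                f"(got {offspring} vs {self.population_size})"
            )
        if not (0 <= self.mutation_prob <= 1):
            raise ConfigurationError("mutation_prob must be in [0, 1]")
        if self.restart_elite >= self.population_size or self.restart_elite < 1:
            raise ConfigurationError("restart_elite must be in [1, population_size)")
        if self.individual_size < 1:
            raise ConfigurationError("individual_size must be positive")
        if self.mutation_strategy not in ("best_copy", "child"):
            raise ConfigurationError(
                f"unknown mutation_strategy {self.mutation_strategy!r}"
            )
        if self.n_iterations < 0 or self.restart_period < 1:
            raise ConfigurationError("n_iterations >= 0 and restart_period >= 1 required")


@dataclass
class GATrace:
    """Per-iteration best individuals plus the final ranked population."""

    iterations: list[tuple[int, float, tuple[str, ...]]]
    final_population: list[Individual]
    best: Individual
    config: GAConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"iteration": i, "best_fitness": f, "best_features": ";".join(feats)}
                for i, f, feats in self.iterations
            ]
        )


def make_scorer(
    train_table: pd.DataFrame,
    train_labels: Sequence[str],
    classifier_spec: ClassifierSpec,
) -> Callable[[tuple[str, ...]], float]:
    """Fitness function: train F_1/2 of the classifier on a feature subset.

    Fits on the training rows restricted to the subset and scores predictions
    on those same rows (no inner validation split). Memoized on the feature
    set; equivalent to `modeling.fit(...)` followed by a confusion on the
    training rows.
    """
    y = np.asarray(train_labels, dtype=object)
    if len(set(y)) < 2:
        raise ScoringError("training labels contain a single class")
    matrix = train_table.to_numpy(dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ScoringError("training table contains non-finite values")
    col_of = {str(c): j for j, c in enumerate(train_table.columns)}
    threshold = classifier_spec.probability_threshold
    cache: dict[frozenset, float] = {}

    def score(features: tuple[str, ...]) -> float:
        key = frozenset(features)
        hit = cache.get(key)
        if hit is not None:
            return hit
        try:
            cols = [col_of[f] for f in features]
        except KeyError as exc:
            raise ScoringError(f"feature {exc.args[0]!r} not in training table")
        X = matrix[:, cols]
        if classifier_spec.scale_features:
            X = StandardScaler().fit_transform(X)
        try:
            # inputs are validated once up front; skip sklearn's per-fit checks
            with config_context(assume_finite=True, skip_parameter_validation=True):
                est = _backend(classifier_spec).fit(X, y)
                pos_col = list(est.classes_).index(POSITIVE_LABEL)
                proba = est.predict_proba(X)[:, pos_col]
            pred = np.where(proba >= threshold, POSITIVE_LABEL, NEGATIVE_LABEL).astype(object)
            fitness = f_beta(confusion(y, pred), 0.5)
        except Exception:
            # degenerate subsets (e.g. no within-class variation anywhere)
            # cannot beat anything: score like an all-majority predictor
            logger.debug("degenerate fit for %s; fitness 0", features)
            fitness = 0.0
        cache[key] = fitness
        return fitness

    return score


def score_individual(
    ind: Individual,
    train_table: pd.DataFrame,
    train_labels: Sequence[str],
    classifier_spec: ClassifierSpec,
) -> float:
    """One-off fitness of an individual (see :func:`make_scorer`)."""
    return make_scorer(train_table, train_labels, classifier_spec)(ind.features)


def _rank_key(ind: Individual):
    return (-(ind.fitness if ind.fitness is not None else -1.0), ind.key)


def _random_individual(pool: np.ndarray, k: int, rng: np.random.Generator) -> Individual:
    feats = rng.choice(pool, size=k, replace=False)
    return Individual(features=tuple(str(f) for f in feats))


def init_population(
    pool: Sequence[str],
    config: GAConfig,
    rng: np.random.Generator,
    scorer: Callable[[tuple[str, ...]], float],
) -> list[Individual]:
    """Random scored population, ranked by fitness (ties: lexicographic set)."""
    pool_arr = np.asarray(list(pool), dtype=object)
    if len(pool_arr) < config.individual_size:
        raise ConfigurationError(
            f"pool of {len(pool_arr)} features cannot form individuals of size "
            f"{config.individual_size}"
        )
    pop = [
        _random_individual(pool_arr, config.individual_size, rng)
        for _ in range(config.population_size)
    ]
    pop = [replace(ind, fitness=scorer(ind.features)) for ind in pop]
    pop.sort(key=_rank_key)
    return pop


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    rng: np.random.Generator,
    pool: Sequence[str],
) -> Individual:
    """First half of one parent plus the complementary half of the other.

    The child takes positions 1..3 from *parent_a* and positions 4..6 from
    *parent_b* (so every gene position is transmissible — parents are drawn
    in both roles); duplicate names are replaced by uniform pool draws until
    the child has six distinct features.
    """
    k = len(parent_a.features)
    half = k // 2
    child: list[str] = []
    for f in parent_a.features[:half] + parent_b.features[half:]:
        if f not in child:
            child.append(f)
    pool_arr = pool if isinstance(pool, np.ndarray) else np.asarray(list(pool), dtype=object)
    while len(child) < k:
        f = str(pool_arr[rng.integers(len(pool_arr))])
        if f not in child:
            child.append(f)
    return Individual(features=tuple(child))


def mutate(
    child: Individual,
    best: Individual,
    pool: Sequence[str],
    rng: np.random.Generator,
    mutation_prob: float = 0.2,
    strategy: str = "best_copy",
) -> Individual:
    """With probability *mutation_prob*, jump to the vicinity of *best*.

    Default strategy replaces the child by a copy of the optimal individual
    with two uniformly chosen positions overwritten by random pool features
    (re-drawn on collision). The "child" strategy instead randomizes two
    positions of the child itself.
    """
    if rng.random() >= mutation_prob:
        return child
    source = best if strategy == "best_copy" else child
    feats = list(source.features)
    k = len(feats)
    positions = rng.choice(k, size=min(2, k), replace=False)
    pool_arr = pool if isinstance(pool, np.ndarray) else np.asarray(list(pool), dtype=object)
    for pos in positions:
        while True:
            f = str(pool_arr[rng.integers(len(pool_arr))])
            if f not in feats or feats[pos] == f:
                feats[pos] = f
                break
    return Individual(features=tuple(feats))


def evolve(
    train_table: pd.DataFrame,
    train_labels: Sequence[str],
    pool: Sequence[str],
    classifier_spec: ClassifierSpec,
    config: GAConfig,
) -> GATrace:
    """Run the full GA and return its trace.

    Deterministic for a fixed ``config.seed``. The best-so-far individual is
    never displaced (diversity injection skips it; restarts keep the elite),
    so the recorded best fitness is non-decreasing.
    """
    rng = np.random.default_rng(config.seed)
    pool_list = [str(f) for f in pool]
    scorer = make_scorer(train_table, train_labels, classifier_spec)
    pop = init_population(pool_list, config, rng, scorer)
    n = config.population_size
    half = n // 2
    n_div = int(half * config.diversity_fraction)
    pool_arr = np.asarray(pool_list, dtype=object)

    trace: list[tuple[int, float, tuple[str, ...]]] = [
        (0, pop[0].fitness, pop[0].features)
    ]
    for it in range(1, config.n_iterations + 1):
        best = pop[0]
        top_half = pop[:half]
        children = []
        for _ in range(config.n_offspring):
            pa, pb = (top_half[i] for i in rng.integers(0, half, size=2))
            child = crossover(pa, pb, rng, pool_arr)
            child = mutate(
                child, best, pool_arr, rng, config.mutation_prob, config.mutation_strategy
            )
            children.append(replace(child, fitness=scorer(child.features)))
        pop = top_half + children

        # diversity injection into the reproducible (top) half, sparing the
        # best individual; strong injected probes survive the re-rank and
        # reproduce next generation
        if n_div > 0 and half > 1:
            idx = rng.choice(np.arange(1, half), size=min(n_div, half - 1), replace=False)
            for i in idx:
                fresh = _random_individual(pool_arr, config.individual_size, rng)
                pop[i] = replace(fresh, fitness=scorer(fresh.features))

        if it % config.restart_period == 0 and it < config.n_iterations:
            pop.sort(key=_rank_key)
            elite = pop[: config.restart_elite]
            fresh = [
                _random_individual(pool_arr, config.individual_size, rng)
                for _ in range(n - config.restart_elite)
            ]
            fresh = [replace(ind, fitness=scorer(ind.features)) for ind in fresh]
            pop = elite + fresh

        pop.sort(key=_rank_key)
        trace.append((it, pop[0].fitness, pop[0].features))

    return GATrace(iterations=trace, final_population=pop, best=pop[0], config=config)


class GAFeatureSelector(BaseEstimator, SelectorMixin):
    """scikit-learn selector wrapping the GA search.

    ``fit(X, y)`` evolves six-feature individuals to maximize the training
    F_1/2 of the configured classifier family; ``transform`` keeps the winning
    features. Fitted attributes: ``best_features_``, ``best_fitness_``,
    ``trace_``, ``support_``.
    """

    def __init__(
        self,
        family: str = "LDA",
        population_size: int = 1000,
        n_iterations: int = 199,
        mutation_prob: float = 0.2,
        restart_period: int = 50,
        restart_elite: int = 10,
        diversity_fraction: float = 1.0 / 3.0,
        individual_size: int = 6,
        mutation_strategy: str = "best_copy",
        probability_threshold: float = 0.5,
        seed: int = 0,
    ):
        self.family = family
        self.population_size = population_size
        self.n_iterations = n_iterations
        self.mutation_prob = mutation_prob
        self.restart_period = restart_period
        self.restart_elite = restart_elite
        self.diversity_fraction = diversity_fraction
        self.individual_size = individual_size
        self.mutation_strategy = mutation_strategy
        self.probability_threshold = probability_threshold
        self.seed = seed

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            n_iterations=self.n_iterations,
            mutation_prob=self.mutation_prob,
            restart_period=self.restart_period,
            restart_elite=self.restart_elite,
            diversity_fraction=self.diversity_fraction,
            individual_size=self.individual_size,
            mutation_strategy=self.mutation_strategy,
            seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y) -> "GAFeatureSelector":
        X = pd.DataFrame(X)
        spec = ClassifierSpec(
            family=self.family, probability_threshold=self.probability_threshold,
            seed=self.seed,
        )
        trace = evolve(X, y, [str(c) for c in X.columns], spec, self._config())
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        self.trace_ = trace
        self.best_features_ = list(trace.best.features)
        self.best_fitness_ = trace.best.fitness
        chosen = set(self.best_features_)
        self.support_ = np.asarray(
            [c in chosen for c in self.feature_names_in_], dtype=bool
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return X.loc[:, self.best_features_]


__all__ = [
    "Individual",
    "GAConfig",
    "GATrace",
    "ConfigurationError",
    "ScoringError",
    "make_scorer",
    "score_individual",
    "init_population",
    "crossover",
    "mutate",
    "evolve",
    "GAFeatureSelector",
]
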