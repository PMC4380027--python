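"""Genetic-algorithm feature-subset selection over k-means clustering.

A chromosome is a bitmask over the candidate features.  Its fitness —
minimized — is

    fitness = 1 - F + m / N

where F is the F-measure of the class-mean-initialized k-means
clustering on the selected columns, m the number of selected features
and N the candidate count.  The regularization term drives the search
toward the smallest feature subset that still clusters the target
family into one clean cluster.

The GA is generational with tournament selection (size 2), uniform
crossover, independent per-bit mutation and single-individual elitism;
defaults follow the study protocol: population 1000, 1000 generations,
crossover rate 0.8, mutation rate 0.01.  All randomness flows from one
seeded generator, so runs are bit-reproducible.

:func:`select_for_family` wraps the GA in the outer parameter grid —
terminal lengths d_N in {10, 12, 14, 16}, d_C in {8, 10} and cluster
counts K = 2..15 — rebuilding the family feature space per (d_N, d_C)
cell and keeping the grid cell with the best F-measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cluster_eval import EvaluationMetrics, cluster, evaluate
from .io_formats import AAIndexTable, Peptide
from .physchem import PrunedTable, RestrictiveProperty, build_family_feature_space
from .preprocess import LabeledMatrix, prepare

WORST_FITNESS = 2.0  # empty chromosome: 1 - 0 + penalty cap

DEFAULT_D_N_GRID = (10, 12, 14, 16)
DEFAULT_D_C_GRID = (8, 10)
DEFAULT_K_GRID = tuple(range(2, 16))


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 1000
    generations: int = 1000
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    elitism: int = 1
    tournament_size: int = 2
    init_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "init_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("population_size and generations must be >= 1")


@dataclass
class SelectionResult:
    """Best chromosome found, with its clustering quality and provenance."""

    mask: np.ndarray  # bool mask over candidate features
    feature_names: list[str]
    K: int
    d_N: int
    d_C: int
    fitness: float
    metrics: EvaluationMetrics
    fitness_trace: list[float] = field(default_factory=list)
    restrictive: list[RestrictiveProperty] = field(default_factory=list)

    @property
    def selected_features(self) -> list[str]:
        return [f for f, b in zip(self.feature_names, self.mask) if b]

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def fitness(
    mask: np.ndarray,
    matrix: LabeledMatrix,
    K: int,
    seed: int = 0,
) -> tuple[float, EvaluationMetrics | None]:
    """Fitness of one chromosome: 1 - F-measure + m/N.

    An all-zero chromosome scores the worst-case 2.0 without clustering.
    """
    mask = np.asarray(mask, dtype=bool)
    N = mask.size
    m = int(mask.sum())
    if m == 0:
        return WORST_FITNESS, None
    sub = LabeledMatrix(
        X=matrix.X[:, mask],
        y=matrix.y,
        feature_names=[f for f, b in zip(matrix.feature_names, mask) if b],
        peptide_ids=matrix.peptide_ids,
    )
    result = cluster(sub, K, seed=seed)
    metrics = evaluate(result, matrix.y)
    return 1.0 - metrics.f_measure + m / N, metrics


def run_ga(
    matrix: LabeledMatrix,
    K: int,
    config: GAConfig | None = None,
) -> SelectionResult:
    """Evolve feature subsets; return the best-ever chromosome.

    Deterministic for a given (matrix, K, config): the config seed drives
    population initialization, selection, crossover, mutation and the
    k-means seed used inside the fitness evaluation.
    """
    if config is None:
        config = GAConfig()
    rng = np.random.default_rng(config.seed)
    kmeans_seed = int(
        np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0]
        % (2**31)
    )
    N = len(matrix.feature_names)
    pop = rng.random((config.population_size, N)) < config.init_prob

    cache: dict[bytes, tuple[float, EvaluationMetrics | None]] = {}

    def evaluate_mask(mask: np.ndarray) -> tuple[float, EvaluationMetrics | None]:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = fitness(mask, matrix, K, seed=kmeans_seed)
        return cache[key]

    best_mask: np.ndarray | None = None
    best_fit = np.inf
    best_metrics: EvaluationMetrics | None = None
    trace: list[float] = []

    for _gen in range(config.generations):
        fits = np.empty(config.population_size)
        for i in range(config.population_size):
            f, metr = evaluate_mask(pop[i])
            fits[i] = f
            if f < best_fit:
                best_fit, best_mask, best_metrics = f, pop[i].copy(), metr
        trace.append(best_fit)

        # tournament selection of parents
        n_parents = config.population_size
        contenders = rng.integers(
            0, config.population_size, size=(n_parents, config.tournament_size)
        )
        parents = pop[
            contenders[np.arange(n_parents), fits[contenders].argmin(axis=1)]
        ].copy()

        # uniform crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, n_parents - 1, 2):
            if rng.random() < config.crossover_rate:
                swap = rng.random(N) < 0.5
                a, b = children[i].copy(), children[i + 1].copy()
                children[i, swap], children[i + 1, swap] = b[swap], a[swap]

        # per-bit mutation
        flips = rng.random(children.shape) < config.mutation_rate
        children ^= flips

        # elitism: best-ever individuals survive unchanged
        if config.elitism > 0 and best_mask is not None:
            order = fits.argsort()
            for e in range(min(config.elitism, config.population_size)):
                children[e] = pop[order[e]]
            children[0] = best_mask
        pop = children

    # final population sweep
    for i in range(config.population_size):
        f, metr = evaluate_mask(pop[i])
        if f < best_fit:
            best_fit, best_mask, best_metrics = f, pop[i].copy(), metr
    trace.append(best_fit)

    if best_mask is None or best_metrics is None:
        raise RuntimeError("GA produced no evaluable chromosome")
    return SelectionResult(
        mask=best_mask,
        feature_names=list(matrix.feature_names),
        K=-1,
        d_N=-1,
        d_C=-1,
        fitness=float(best_fit),
        metrics=best_metrics,
        fitness_trace=trace,
    )


def _better(cand: SelectionResult, incumbent: SelectionResult | None) -> bool:
    """Grid-cell comparison: higher F, then fewer features, then smaller
    K, d_N, d_C."""
    if incumbent is None:
        return True
    a = (
        -cand.metrics.f_measure,
        cand.n_selected,
        cand.K,
        cand.d_N,
        cand.d_C,
    )
    b = (
        -incumbent.metrics.f_measure,
        incumbent.n_selected,
        incumbent.K,
        incumbent.d_N,
        incumbent.d_C,
    )
    return a < b


def select_for_family(
    target_family: str,
    all_peptides: list[Peptide],
    table: PrunedTable | AAIndexTable | None,
    d_N_grid: tuple[int, ...] = DEFAULT_D_N_GRID,
    d_C_grid: tuple[int, ...] = DEFAULT_D_C_GRID,
    K_grid: tuple[int, ...] = DEFAULT_K_GRID,
    config: GAConfig | None = None,
    coverage_threshold: float = 0.9,
    mode: str = "mined",
    min_family_size: int = 11,
) -> SelectionResult:
    """Grid-search (d_N, d_C, K) around the GA for one target family.

    For every (d_N, d_C) cell the family feature space is rebuilt
    (mining restrictive properties from the target family at that
    layout), preprocessed, and the GA run once per K.  The winner is the
    cell with the highest F-measure; ties prefer fewer selected
    features, then smaller K, d_N, d_C.  Families below
    ``min_family_size`` peptides are rejected (relax via the argument).
    """
    if config is None:
        config = GAConfig()
    if not d_N_grid or not d_C_grid or not K_grid:
        raise ValueError("empty parameter grid")
    n_family = sum(1 for p in all_peptides if p.family == target_family)
    if n_family < min_family_size:
        raise ValueError(
            f"family {target_family!r} has {n_family} peptides "
            f"(< {min_family_size}); pass min_family_size to relax"
        )
    best: SelectionResult | None = None
    for d_N in d_N_grid:
        for d_C in d_C_grid:
            fm, restrictive = build_family_feature_space(
                target_family,
                all_peptides,
                d_N,
                d_C,
                table,
                coverage_threshold=coverage_threshold,
                mode=mode,
            )
            labeled, _, _ = prepare(fm, target_family)
            for K in K_grid:
                res = run_ga(labeled, K, config)
                res = replace(
                    res, K=K, d_N=d_N, d_C=d_C, restrictive=restrictive
                )
                if _better(res, best):
                    best = res
    assert best is not None
    return best
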