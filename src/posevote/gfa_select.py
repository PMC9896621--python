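"""Genetic-algorithm descriptor selection with Cohen's kappa as fitness.

Each candidate model is a binary chromosome over descriptor columns; fitness
is the cross-validated kappa of a tree learner restricted to the selected
columns.  Selection runs in two phases: a broad phase that narrows the
descriptor pool to 50 columns by selection frequency in the final population,
and a refinement phase whose soft cardinality penalty steers the best
chromosome into the 10–20 descriptor range.

Operator choices (tournament selection of size 3, uniform crossover, per-gene
mutation at 1/length, single elitism) are standard and configurable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ml_engine import FeatureMatrix, cv_metrics, make_learner, partition_rows
from .labeling_split import SplitAssignment

ALL_ZERO_FITNESS = -1.0  # sentinel: an empty model is worst possible


@dataclass
class Chromosome:
    genes: np.ndarray  # binary vector over candidate columns
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int8)
        if not np.isin(self.genes, (0, 1)).all():
            raise ValueError("genes must be binary")

    @property
    def n_selected(self) -> int:
        return int(self.genes.sum())

    def selected_columns(self, columns: Sequence[str]) -> list[str]:
        return [c for c, g in zip(columns, self.genes) if g]

    def key(self) -> bytes:
        return self.genes.tobytes()


@dataclass
class GfaConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # None -> 1/length per gene
    elitism_count: int = 1
    seed: int = 0
    learner: str = "rf"
    target_descriptor_range: tuple[int, int] | None = None
    cardinality_penalty: float = 0.05
    tournament_size: int = 3
    init_density: float = 0.15
    cv_folds: int = 5
    fast_learner: bool = True
    fitness_trees: int | None = None  # override ensemble size for fitness only
    max_fitness_rows: int | None = None  # subsample training rows for fitness

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for rate in (self.crossover_rate, self.mutation_rate):
            if rate is not None and not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.learner not in ("rf", "xgb"):
            raise ValueError("GFA learner must be 'rf' or 'xgb'")


# desk-scale presets keep the search far smaller than the published schedule
# (50×100 then 500×5000) so a full recovery study fits a single CPU budget.
PRESETS: dict[str, dict] = {
    "paper": {
        "phase1": {"population_size": 50, "generations": 100},
        "phase2": {"population_size": 500, "generations": 5000},
        "cv_folds": 5,
    },
    "desk": {
        "phase1": {"population_size": 20, "generations": 10},
        "phase2": {"population_size": 20, "generations": 15},
        "cv_folds": 3,
        "fitness_trees": 15,
        "max_fitness_rows": 500,
    },
}

PHASE1_TARGET_COLUMNS = 50
PHASE2_RANGE = (10, 20)


def evaluate_fitness(
    chrom: Chromosome,
    matrix: FeatureMatrix,
    split: SplitAssignment,
    learner: str = "rf",
    seed: int = 0,
    cv_folds: int = 5,
    penalty_range: tuple[int, int] | None = None,
    penalty_weight: float = 0.05,
    fast_learner: bool = True,
    fitness_trees: int | None = None,
    max_fitness_rows: int | None = None,
) -> float:
    """Cross-validated kappa of the learner on the chromosome's columns.

    An all-zero chromosome gets the ``-1`` sentinel rather than raising.  When
    ``penalty_range = (lo, hi)`` is given, a soft cardinality penalty
    ``weight * max(0, n - hi) + weight * max(0, lo - n)`` is subtracted.
    ``fitness_trees`` / ``max_fitness_rows`` trade fidelity for speed inside
    the GA loop only (final reported models are refit at full size).
    """
    n_sel = chrom.n_selected
    if n_sel == 0:
        return ALL_ZERO_FITNESS
    train_mask, _ = partition_rows(matrix, split)
    X = matrix.X[train_mask][:, chrom.genes.astype(bool)]
    y = matrix.y()[train_mask]
    if max_fitness_rows is not None and X.shape[0] > max_fitness_rows:
        sub_rng = np.random.default_rng(seed)
        idx = np.sort(
            sub_rng.choice(X.shape[0], size=max_fitness_rows, replace=False)
        )
        X, y = X[idx], y[idx]
    estimator = _fitness_estimator(learner, seed, fast_learner, fitness_trees)
    _, kappa = cv_metrics(estimator, X, y, seed=seed, n_splits=cv_folds)
    if penalty_range is not None:
        lo, hi = penalty_range
        kappa -= penalty_weight * max(0, n_sel - hi)
        kappa -= penalty_weight * max(0, lo - n_sel)
    return float(kappa)


def _fitness_estimator(
    learner: str, seed: int, fast_learner: bool, fitness_trees: int | None
):
    if fitness_trees is None:
        return make_learner(learner, seed=seed, fast=fast_learner)
    if learner == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=fitness_trees, random_state=seed, n_jobs=1
        )
    from sklearn.ensemble import HistGradientBoostingClassifier

    return HistGradientBoostingClassifier(max_iter=fitness_trees, random_state=seed)


@dataclass
class GfaResult:
    best: Chromosome
    history: list[float] = field(default_factory=list)  # best fitness per generation
    final_population: list[Chromosome] = field(default_factory=list)
    n_evaluations: int = 0


def run_gfa(
    matrix: FeatureMatrix,
    split: SplitAssignment,
    config: GfaConfig,
    initial_population: Sequence[Chromosome] | None = None,
) -> GfaResult:
    """Evolve chromosomes over the matrix columns; return the best ever seen.

    With ``elitism_count >= 1`` the best fitness is non-decreasing across
    generations.  Identical chromosomes share one cached fitness evaluation,
    so the run is deterministic in (config, seed, matrix, split).
    """
    n_cols = matrix.X.shape[1]
    if n_cols < 2:
        raise ValueError("need at least 2 candidate columns")
    rng = random.Random(config.seed)
    np_rng = np.random.default_rng(config.seed)
    mutation_rate = (
        config.mutation_rate if config.mutation_rate is not None else 1.0 / n_cols
    )

    cache: dict[bytes, float] = {}
    n_evaluations = 0

    def fitness_of(chrom: Chromosome) -> float:
        nonlocal n_evaluations
        key = chrom.key()
        if key not in cache:
            cache[key] = evaluate_fitness(
                chrom,
                matrix,
                split,
                learner=config.learner,
                seed=config.seed,
                cv_folds=config.cv_folds,
                penalty_range=config.target_descriptor_range,
                penalty_weight=config.cardinality_penalty,
                fast_learner=config.fast_learner,
                fitness_trees=config.fitness_trees,
                max_fitness_rows=config.max_fitness_rows,
            )
            n_evaluations += 1
        return cache[key]

    if initial_population is not None:
        population = [Chromosome(genes=c.genes.copy()) for c in initial_population]
        if len(population) != config.population_size:
            raise ValueError("initial population size mismatch with config")
    else:
        population = []
        for _ in range(config.population_size):
            genes = (np_rng.random(n_cols) < config.init_density).astype(np.int8)
            if genes.sum() == 0:
                genes[np_rng.integers(n_cols)] = 1
            population.append(Chromosome(genes=genes))

    for chrom in population:
        chrom.fitness = fitness_of(chrom)

    def tournament() -> Chromosome:
        contenders = rng.sample(population, min(config.tournament_size, len(population)))
        return max(contenders, key=lambda c: c.fitness)

    best = max(population, key=lambda c: c.fitness)
    best = Chromosome(genes=best.genes.copy(), fitness=best.fitness)
    history: list[float] = []

    for _ in range(config.generations):
        elite = sorted(population, key=lambda c: -c.fitness)[: config.elitism_count]
        offspring: list[Chromosome] = [
            Chromosome(genes=e.genes.copy(), fitness=e.fitness) for e in elite
        ]
        while len(offspring) < config.population_size:
            a, b = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                mask = np_rng.random(n_cols) < 0.5
                child_genes = np.where(mask, a.genes, b.genes).astype(np.int8)
            else:
                child_genes = a.genes.copy()
            flip = np_rng.random(n_cols) < mutation_rate
            child_genes = np.where(flip, 1 - child_genes, child_genes).astype(np.int8)
            offspring.append(Chromosome(genes=child_genes))
        population = offspring
        for chrom in population:
            if chrom.fitness is None:
                chrom.fitness = fitness_of(chrom)
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = Chromosome(genes=gen_best.genes.copy(), fitness=gen_best.fitness)
        history.append(gen_best.fitness)

    return GfaResult(
        best=best,
        history=history,
        final_population=population,
        n_evaluations=n_evaluations,
    )


def truncate_by_frequency(
    result: GfaResult,
    columns: Sequence[str],
    n_keep: int = PHASE1_TARGET_COLUMNS,
) -> list[str]:
    """Keep the ``n_keep`` columns most often selected in the final population.

    Ties break by selection frequency within the best-fitness decile of the
    population, then by column order — fully deterministic.
    """
    population = result.final_population
    genes = np.stack([c.genes for c in population])
    freq = genes.sum(axis=0)
    n_decile = max(1, len(population) // 10)
    decile = sorted(population, key=lambda c: -(c.fitness or ALL_ZERO_FITNESS))[:n_decile]
    decile_freq = np.stack([c.genes for c in decile]).sum(axis=0)
    order = sorted(
        range(len(columns)),
        key=lambda i: (-freq[i], -decile_freq[i], i),
    )
    kept_idx = sorted(order[:n_keep])
    return [columns[i] for i in kept_idx]


def two_phase_select(
    matrix: FeatureMatrix,
    split: SplitAssignment,
    learner: str = "rf",
    seed: int = 0,
    preset: str = "desk",
    phase2_range: tuple[int, int] = PHASE2_RANGE,
) -> tuple[list[str], dict]:
    """Broad-then-refine GA selection; returns (final columns, run details).

    Phase 1 truncates the pool to 50 columns by final-population frequency
    (skipped with a notice when the matrix has fewer than 50 columns);
    phase 2 searches that pool under the 10–20 cardinality penalty.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    sizes = PRESETS[preset]
    details: dict = {"preset": preset, "phase1_skipped": False}

    work = matrix
    if matrix.X.shape[1] < PHASE1_TARGET_COLUMNS:
        details["phase1_skipped"] = True
        details["notice"] = (
            f"{matrix.X.shape[1]} candidate columns < {PHASE1_TARGET_COLUMNS}; "
            "phase 1 skipped"
        )
    else:
        cfg1 = GfaConfig(
            seed=seed,
            learner=learner,
            cv_folds=sizes["cv_folds"],
            fitness_trees=sizes.get("fitness_trees"),
            max_fitness_rows=sizes.get("max_fitness_rows"),
            **sizes["phase1"],
        )
        res1 = run_gfa(work, split, cfg1)
        phase1_columns = truncate_by_frequency(res1, work.columns)
        details["phase1_columns"] = phase1_columns
        details["phase1_history"] = res1.history
        details["phase1_evaluations"] = res1.n_evaluations
        work = work.subset_columns(phase1_columns)

    cfg2 = GfaConfig(
        seed=seed + 1,
        learner=learner,
        cv_folds=sizes["cv_folds"],
        fitness_trees=sizes.get("fitness_trees"),
        max_fitness_rows=sizes.get("max_fitness_rows"),
        target_descriptor_range=phase2_range,
        init_density=min(0.5, phase2_range[1] / max(1, work.X.shape[1])),
        **sizes["phase2"],
    )
    res2 = run_gfa(work, split, cfg2)
    final = res2.best.selected_columns(work.columns)
    details["phase2_history"] = res2.history
    details["phase2_evaluations"] = res2.n_evaluations
    details["phase2_fitness"] = res2.best.fitness
    return final, details
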