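"""Two-phase evolutionary architecture search.

Phase 1 is a coarse multi-population (island-model) search: one
subpopulation per depth, short fitness trainings, and per generation the
sequence evaluate -> select top half -> refill by crossover + mutation ->
(on schedule) migrate and truncate to the elite.  Fitness of retained
genomes is cached rather than retrained, so the per-depth best can never
regress.  Phase 2 refines the phase-1 winner as an elite-of-one lineage
with long, early-stopped trainings, and reports k-fold cross-validation
of the final genome.

``EvolutionarySearch`` packages both phases behind a scikit-learn-style
``fit(X, y)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from functools import partial
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .genome import (
    FilterCatalog,
    Genome,
    GenomeBounds,
    default_catalog,
    sample_initial_population,
    serialize_genome,
    validate_genome,
)
from .migration import MigrationConfig, MigrationEvent, migrate
from .operators import (
    FitnessRecord,
    OperatorConfig,
    adjusted_score,
    average_fitness,
    crossover,
    has_converged,
    mutate,
    select_top_half,
)
from .phantom import SegmentationDataset
from .trainer import TrainConfig, build_model, kfold_cv, train

__all__ = [
    "GAConfig",
    "GenerationRecord",
    "EvolutionHistory",
    "make_training_evaluator",
    "evaluate_fitness_parallel",
    "run_phase1",
    "run_phase2",
    "EvolutionarySearch",
]

# An evaluator maps (genome, dataset, epochs, seed) -> best validation Dice.
Evaluator = Callable[[Genome, SegmentationDataset, int, int], float]


@dataclass(frozen=True)
class GAConfig:
    """All hyperparameters of the evolutionary run."""

    bounds: GenomeBounds = field(default_factory=GenomeBounds)
    operators: OperatorConfig = field(default_factory=OperatorConfig)
    migration: MigrationConfig = field(default_factory=MigrationConfig)
    catalog: FilterCatalog = field(default_factory=default_catalog)
    train: TrainConfig = field(default_factory=TrainConfig)
    population_per_depth: int = 6
    max_generations: int = 10
    phase1_epochs: int = 30
    phase2_epochs: int = 300
    phase2_generations: int = 10
    folds: int = 3
    split_fraction: float = 0.8
    seed: int = 0
    parallel_workers: int = 1

    def __post_init__(self) -> None:
        if self.population_per_depth < 2:
            raise ValueError("population_per_depth must be >= 2")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "bounds": {
                "dropout_min": self.bounds.dropout_min,
                "dropout_max": self.bounds.dropout_max,
                "f_min": self.bounds.f_min,
                "f_max": self.bounds.f_max,
                "depth_set": sorted(self.bounds.depth_set),
            },
            "operators": {
                k: getattr(self.operators, k)
                for k in (
                    "mutation_prob", "dropout_delta_bound", "filter_delta_bound",
                    "penalty_factor", "dice_smooth", "convergence_tol",
                    "penalty_mode", "snap_pow2",
                )
            },
            "migration": {
                k: getattr(self.migration, k)
                for k in ("migration_rate", "interval", "retain_after")
            },
            "catalog": {
                int(d): [list(r) for r in rows]
                for d, rows in self.catalog.entries.items()
            },
            "train": {
                k: getattr(self.train, k)
                for k in (
                    "learning_rate", "batch_size", "early_stop_patience",
                    "min_delta", "binarize_threshold",
                )
            },
            **{
                k: getattr(self, k)
                for k in (
                    "population_per_depth", "max_generations", "phase1_epochs",
                    "phase2_epochs", "phase2_generations", "folds",
                    "split_fraction", "seed", "parallel_workers",
                )
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GAConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        kwargs = dict(payload)
        if "bounds" in kwargs:
            b = dict(kwargs.pop("bounds"))
            if "depth_set" in b:
                b["depth_set"] = frozenset(b["depth_set"])
            kwargs["bounds"] = GenomeBounds(**b)
        if "operators" in kwargs:
            kwargs["operators"] = OperatorConfig(**kwargs.pop("operators"))
        if "migration" in kwargs:
            kwargs["migration"] = MigrationConfig(**kwargs.pop("migration"))
        if "catalog" in kwargs:
            kwargs["catalog"] = FilterCatalog(
                entries={
                    int(d): tuple(tuple(r) for r in rows)
                    for d, rows in kwargs.pop("catalog").items()
                }
            )
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs.pop("train"))
        return cls(**kwargs)


@dataclass
class GenerationRecord:
    generation: int
    best_by_depth: dict[int, FitnessRecord]
    avg_by_depth: dict[int, float]
    avg_overall: float
    migration_events: list[MigrationEvent] = field(default_factory=list)


@dataclass
class EvolutionHistory:
    """Complete record of a phase-1 run."""

    generations: list[GenerationRecord] = field(default_factory=list)
    evaluations: list[FitnessRecord] = field(default_factory=list)
    overall_winner: FitnessRecord | None = None

    def generation_table(self) -> pd.DataFrame:
        """Per-generation best architecture per depth (depth, filters,
        adjusted score) -- one row per (generation, depth)."""
        rows = []
        for gen in self.generations:
            for depth in sorted(gen.best_by_depth):
                rec = gen.best_by_depth[depth]
                rows.append(
                    {
                        "generation": gen.generation,
                        "depth": depth,
                        "filters": str(list(rec.genome.filters)),
                        "dice": rec.dice,
                        "adjusted_score": rec.adjusted,
                    }
                )
        return pd.DataFrame(rows)

    def to_jsonl(self, path) -> None:
        """One JSON line per fitness evaluation."""
        with open(path, "w") as fh:
            for rec in self.evaluations:
                fh.write(
                    json.dumps(
                        {
                            "generation": rec.generation,
                            "depth": rec.subpopulation_depth,
                            "dice": rec.dice,
                            "adjusted": rec.adjusted,
                            "provisional": rec.provisional,
                            "genome": json.loads(serialize_genome(rec.genome)),
                        }
                    )
                    + "\n"
                )

    @staticmethod
    def read_jsonl(path) -> pd.DataFrame:
        return pd.read_json(path, lines=True)


def genome_seed(run_seed: int, genome: Genome) -> int:
    """Deterministic per-genome training seed, independent of worker
    scheduling: a hash of the run seed and the canonical serialization."""
    digest = hashlib.sha256(
        f"{run_seed}|{serialize_genome(genome)}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _train_and_score(
    genome: Genome,
    dataset: SegmentationDataset,
    epochs: int,
    seed: int,
    split_fraction: float,
    base: TrainConfig,
) -> float:
    """Default fitness: train on a seeded split, return best val Dice."""
    rng = np.random.default_rng(seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_train = max(1, min(n - 1, int(round(split_fraction * n))))
    train_ds = dataset.subset(order[:n_train])
    val_ds = dataset.subset(order[n_train:])
    h, w = dataset.images.shape[1:]
    model = build_model(genome, (h, w), seed=seed)
    cfg = replace(base, max_epochs=epochs, seed=seed)
    _, best_dice, _ = train(model, train_ds, val_ds, cfg)
    return best_dice


def make_training_evaluator(cfg: GAConfig) -> Evaluator:
    """The standard evaluator: short seeded training on an 80/20 split."""
    return partial(
        _train_and_score, split_fraction=cfg.split_fraction, base=cfg.train
    )


def _evaluate_one(
    genome: Genome,
    dataset: SegmentationDataset,
    epochs: int,
    seed: int,
    evaluator: Evaluator,
) -> float:
    try:
        return float(evaluator(genome, dataset, epochs, seed))
    except Exception:
        try:  # one retry, then abort naming the genome
            return float(evaluator(genome, dataset, epochs, seed))
        except Exception as exc:
            raise RuntimeError(
                f"fitness evaluation failed for genome "
                f"{serialize_genome(genome)}: {exc}"
            ) from exc


def evaluate_fitness_parallel(
    genomes: Sequence[Genome],
    dataset: SegmentationDataset,
    epochs: int,
    workers: int,
    seed: int,
    evaluator: Evaluator,
    generation: int = 1,
    op_cfg: OperatorConfig | None = None,
) -> list[FitnessRecord]:
    """Evaluate genomes independently, order-preserving.

    Per-genome seeds derive from (run seed, genome serialization), so the
    result is identical for any worker count given a deterministic
    evaluator.  A failing evaluation is retried once.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    op_cfg = op_cfg or OperatorConfig()
    seeds = [genome_seed(seed, g) for g in genomes]
    dices = Parallel(n_jobs=workers)(
        delayed(_evaluate_one)(g, dataset, epochs, s, evaluator)
        for g, s in zip(genomes, seeds)
    )
    return [
        FitnessRecord(
            genome=g,
            dice=dice,
            adjusted=adjusted_score(
                dice, g.depth, op_cfg.penalty_factor, op_cfg.penalty_mode
            ),
            generation=generation,
            subpopulation_depth=g.depth,
        )
        for g, dice in zip(genomes, dices)
    ]


def _spawn_offspring(
    retained: Sequence[FitnessRecord],
    count: int,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[Genome]:
    offspring = []
    parents = [r.genome for r in retained]
    for _ in range(count):
        if len(parents) == 1:
            p1 = p2 = parents[0]
        else:
            i, j = rng.choice(len(parents), size=2, replace=False)
            p1, p2 = parents[i], parents[j]
        child = crossover(p1, p2, rng, cfg.bounds)
        child = mutate(child, cfg.operators, cfg.bounds, rng)
        offspring.append(child)
    return offspring


def run_phase1(
    cfg: GAConfig,
    dataset: SegmentationDataset,
    evaluator: Evaluator | None = None,
) -> EvolutionHistory:
    """Multi-population coarse search.

    One subpopulation per configured depth, seeded from the catalog.  Each
    generation evaluates every not-yet-scored genome (retained genomes
    keep their cached fitness), records per-depth bests and averages,
    then selects the top half, refills by crossover + mutation, and every
    ``migration.interval`` generations migrates and truncates to the
    elite.  Stops at ``max_generations`` or when the all-population
    average fitness converges.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    evaluator = evaluator or make_training_evaluator(cfg)
    rng = np.random.default_rng(cfg.seed)
    depths = sorted(cfg.bounds.depth_set)
    pops: dict[int, list[Genome]] = {
        d: sample_initial_population(
            d, cfg.catalog, cfg.population_per_depth, rng, cfg.bounds
        )
        for d in depths
    }
    cache: dict[str, float] = {}
    history = EvolutionHistory()
    avg_overall: list[float] = []
    for gen in range(1, cfg.max_generations + 1):
        pending, seen = [], set()
        for d in depths:
            for g in pops[d]:
                key = serialize_genome(g)
                if key not in cache and key not in seen:
                    seen.add(key)
                    pending.append(g)
        for g in pending:
            bad = validate_genome(g, cfg.bounds)
            if bad:
                raise ValueError(f"invalid genome reached evaluation: {bad}")
        new_records = evaluate_fitness_parallel(
            pending, dataset, cfg.phase1_epochs, cfg.parallel_workers,
            cfg.seed, evaluator, generation=gen, op_cfg=cfg.operators,
        )
        for rec in new_records:
            cache[serialize_genome(rec.genome)] = rec.dice
        history.evaluations.extend(new_records)
        records_by_depth = {
            d: [
                FitnessRecord(
                    genome=g,
                    dice=cache[serialize_genome(g)],
                    adjusted=adjusted_score(
                        cache[serialize_genome(g)], d,
                        cfg.operators.penalty_factor, cfg.operators.penalty_mode,
                    ),
                    generation=gen,
                    subpopulation_depth=d,
                )
                for g in pops[d]
            ]
            for d in depths
        }
        best_by_depth = {
            d: select_top_half(records_by_depth[d])[1] for d in depths
        }
        avg_by_depth = {
            d: average_fitness([r.dice for r in records_by_depth[d]])
            for d in depths
        }
        all_records = [r for d in depths for r in records_by_depth[d]]
        avg_overall.append(average_fitness([r.dice for r in all_records]))
        gen_record = GenerationRecord(
            generation=gen,
            best_by_depth=best_by_depth,
            avg_by_depth=avg_by_depth,
            avg_overall=avg_overall[-1],
        )
        history.generations.append(gen_record)
        if gen == cfg.max_generations or has_converged(
            avg_overall, cfg.operators.convergence_tol
        ):
            break
        # Selection, then offspring by crossover + mutation.
        next_pops: dict[int, list[Genome]] = {}
        retained_by_depth: dict[int, list[FitnessRecord]] = {}
        offspring_by_depth: dict[int, list[Genome]] = {}
        for d in depths:
            retained, _ = select_top_half(records_by_depth[d])
            retained_by_depth[d] = retained
            offspring_by_depth[d] = _spawn_offspring(
                retained, cfg.population_per_depth - len(retained), cfg, rng
            )
        if gen % cfg.migration.interval == 0:
            migrated = migrate(
                retained_by_depth, cfg.migration, cfg.catalog, rng,
                cfg.bounds, cfg.operators, events=gen_record.migration_events,
            )
            retained_by_depth = migrated
        for d in depths:
            elite = [r.genome for r in retained_by_depth[d]]
            room = cfg.population_per_depth - len(elite)
            kids = offspring_by_depth[d][: max(room, 0)]
            if room > len(kids):
                kids = kids + _spawn_offspring(
                    retained_by_depth[d], room - len(kids), cfg, rng
                )
            next_pops[d] = elite + kids
        pops = next_pops
    winner = min(
        history.evaluations,
        key=lambda r: (-r.adjusted, serialize_genome(r.genome)),
    )
    history.overall_winner = winner
    return history


def run_phase2(
    winner: Genome,
    cfg: GAConfig,
    dataset: SegmentationDataset,
    evaluator: Evaluator | None = None,
    cv_scorer: Callable[[Genome, SegmentationDataset, int, int], list[float]]
    | None = None,
) -> tuple[Genome, list[float], float, float]:
    """Elite-of-one refinement of the phase-1 winner.

    Each round spawns a mutant and a crossover child (incumbent x mutant),
    evaluates them with long early-stopped training, and keeps the best --
    never worse than the incumbent.  The final genome is scored by
    ``folds``-fold cross-validation; returns (genome, per-fold Dice, mean,
    standard deviation).
    """
    bad = validate_genome(winner, cfg.bounds)
    if bad:
        raise ValueError(f"phase-2 winner genome invalid: {bad}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    evaluator = evaluator or make_training_evaluator(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    incumbent = winner
    incumbent_fit = _evaluate_one(
        incumbent, dataset, cfg.phase2_epochs,
        genome_seed(cfg.seed, incumbent), evaluator,
    )
    for _ in range(cfg.phase2_generations):
        mutant = mutate(incumbent, cfg.operators, cfg.bounds, rng)
        child = crossover(incumbent, mutant, rng, cfg.bounds)
        variants, seen = [], {serialize_genome(incumbent)}
        for v in (mutant, child):
            key = serialize_genome(v)
            if key not in seen:
                seen.add(key)
                variants.append(v)
        if not variants:
            continue
        records = evaluate_fitness_parallel(
            variants, dataset, cfg.phase2_epochs, cfg.parallel_workers,
            cfg.seed, evaluator, op_cfg=cfg.operators,
        )
        best = max(records, key=lambda r: r.dice)
        if best.dice > incumbent_fit:
            incumbent, incumbent_fit = best.genome, best.dice
    if cv_scorer is None:
        cv_cfg = replace(cfg.train, max_epochs=cfg.phase2_epochs, seed=cfg.seed)
        scores, mean, std = kfold_cv(incumbent, dataset, cfg.folds, cv_cfg)
    else:
        scores = list(cv_scorer(incumbent, dataset, cfg.folds, cfg.seed))
        mean, std = float(np.mean(scores)), float(np.std(scores))
    return incumbent, scores, mean, std


class EvolutionarySearch(BaseEstimator):
    """Evolutionary architecture search as a scikit-learn-style estimator.

    ``fit(X, y)`` runs the phase-1 island search on image/mask arrays and,
    when ``refine`` is true, the phase-2 elite-of-one refinement with
    cross-validation.  Fitted attributes: ``history_``, ``best_genome_``
    (phase-1 winner by adjusted score) and, after refinement,
    ``final_genome_``, ``cv_scores_``, ``cv_mean_``, ``cv_std_``.
    """

    def __init__(
        self,
        config: GAConfig | None = None,
        refine: bool = True,
        evaluator: Evaluator | None = None,
    ) -> None:
        self.config = config
        self.refine = refine
        self.evaluator = evaluator

    def fit(self, X, y) -> "EvolutionarySearch":
        cfg = self.config or GAConfig()
        dataset = SegmentationDataset(np.asarray(X), np.asarray(y))
        self.history_ = run_phase1(cfg, dataset, self.evaluator)
        self.best_genome_ = self.history_.overall_winner.genome
        if self.refine:
            final, scores, mean, std = run_phase2(
                self.best_genome_, cfg, dataset, self.evaluator
            )
            self.final_genome_ = final
            self.cv_scores_ = scores
            self.cv_mean_ = mean
            self.cv_std_ = std
        return self
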