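"""Evolutionary operators: Dice fitness, selection, crossover, mutation,
depth-penalized ranking and the convergence test.

Conventions fixed here and relied on elsewhere:

* Fitness is the best validation Dice coefficient of a genome's trained
  network, in ``[0, 1]``.
* Within a (same-depth) subpopulation, selection ranks by raw Dice; the
  depth-penalized *adjusted* score is used only to compare genomes across
  depths.
* All randomness flows through a ``numpy.random.Generator`` so every
  operator is reproducible under a fixed seed, and the draw order inside
  each operator is part of its contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import (
    Genome,
    GenomeBounds,
    clip_to_bounds,
    serialize_genome,
    snap_to_pow2,
)

__all__ = [
    "OperatorConfig",
    "FitnessRecord",
    "MutationEvents",
    "dice_coefficient",
    "average_fitness",
    "select_top_half",
    "crossover",
    "mutate",
    "adjusted_score",
    "has_converged",
]


@dataclass(frozen=True)
class OperatorConfig:
    """Hyperparameters of the evolutionary operators.

    ``mutation_prob`` is the per-event mutation probability: one coin for
    the dropout rate and one independent coin per filter entry.
    ``dropout_delta_bound`` / ``filter_delta_bound`` are the half-widths of
    the uniform perturbations (dropout +- 0.05, filters +- 8).
    ``penalty_factor`` is the depth penalty ``p`` of the adjusted score,
    ``dice_smooth`` the small Dice denominator constant, and
    ``convergence_tol`` the generation-to-generation average-fitness
    tolerance of the stopping rule.
    """

    mutation_prob: float = 0.10
    dropout_delta_bound: float = 0.05
    filter_delta_bound: float = 8.0
    penalty_factor: float = 0.1
    dice_smooth: float = 1e-6
    convergence_tol: float = 1e-3
    penalty_mode: str = "fraction"
    snap_pow2: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.mutation_prob < 1.0:
            raise ValueError("mutation_prob must be in (0, 1)")
        for name in ("dropout_delta_bound", "filter_delta_bound",
                     "penalty_factor", "dice_smooth", "convergence_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.penalty_mode not in ("fraction", "linear"):
            raise ValueError("penalty_mode must be 'fraction' or 'linear'")


@dataclass(frozen=True)
class FitnessRecord:
    """A genome with its evaluated fitness.

    ``dice`` is the best validation Dice, ``adjusted`` the depth-penalized
    score used for cross-depth ranking.  ``provisional`` marks migrant
    records whose fitness was inherited from the source subpopulation's top
    performer and not yet re-evaluated.
    """

    genome: Genome
    dice: float
    adjusted: float
    generation: int
    subpopulation_depth: int
    provisional: bool = False


@dataclass
class MutationEvents:
    """Perturbations applied by one :func:`mutate` call, before clipping.

    ``dropout_delta`` is ``None`` when the dropout coin came up tails;
    ``filter_deltas[i]`` likewise per filter.
    """

    dropout_delta: float | None = None
    filter_deltas: list[float | None] | None = None


def dice_coefficient(mask_true, mask_pred, smooth: float = 1e-6) -> float:
    """Dice similarity of two binary masks.

    ``2 |A & B| / (|A| + |B| + smooth)``; the small ``smooth`` keeps the
    ratio defined when both masks are empty.  Symmetric in its arguments.
    """
    a = np.asarray(mask_true)
    b = np.asarray(mask_pred)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    intersection = np.count_nonzero(a & b)
    total = np.count_nonzero(a) + np.count_nonzero(b)
    return 2.0 * intersection / (total + smooth)


def average_fitness(scores: Sequence[float]) -> float:
    """Arithmetic mean fitness of a population; errors on an empty one."""
    if len(scores) == 0:
        raise ValueError("cannot average an empty list of fitness scores")
    return float(np.mean(scores))


def _selection_key(record: FitnessRecord):
    # Descending fitness; ties broken by the canonical genome serialization
    # so selection is deterministic across runs and platforms.
    return (-record.dice, serialize_genome(record.genome))


def select_top_half(
    population: Sequence[FitnessRecord],
) -> tuple[list[FitnessRecord], FitnessRecord]:
    """Retain the fitter half of a population.

    Returns the ceil(N/2) highest-Dice records sorted descending, plus the
    single winner (the argmax).  At odd N the extra member survives, so a
    lineage can never empty itself.
    """
    if len(population) == 0:
        raise ValueError("cannot select from an empty population")
    ranked = sorted(population, key=_selection_key)
    keep = math.ceil(len(ranked) / 2)
    retained = ranked[:keep]
    return retained, ranked[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def crossover(
    parent1: Genome,
    parent2: Genome,
    rng: np.random.Generator,
    bounds: GenomeBounds | None = None,
    cross_depth: str = "error",
) -> Genome:
    """Blend two parents into a child genome.

    Dropout rates and depths are averaged (depth rounded half-up); filter
    lists are averaged element-wise and rounded; the skip flag is a fair
    coin between the parents' flags.  The child is clipped to bounds.

    Parents normally share a depth (crossover happens inside one
    subpopulation).  ``cross_depth='align'`` permits mixed-depth parents:
    positions are aligned from the shallow end over ``min(d1, d2)`` levels
    and any remaining deep positions of the child come from the deeper
    parent.  ``cross_depth='error'`` (default) rejects mixed-depth pairs.
    """
    bounds = bounds or GenomeBounds()
    if parent1.depth != parent2.depth and cross_depth != "align":
        raise ValueError(
            "crossover parents have different depths "
            f"({parent1.depth} vs {parent2.depth}); use cross_depth='align'"
        )
    child_dropout = (parent1.dropout_rate + parent2.dropout_rate) / 2.0
    child_depth = _round_half_up((parent1.depth + parent2.depth) / 2.0)
    shallow = min(parent1.depth, parent2.depth)
    filters = [
        _round_half_up((parent1.filters[i] + parent2.filters[i]) / 2.0)
        for i in range(min(shallow, child_depth))
    ]
    if child_depth > shallow:
        deeper = parent1 if parent1.depth >= parent2.depth else parent2
        filters.extend(deeper.filters[shallow:child_depth])
    child_skip = parent1.use_skip if rng.integers(0, 2) == 0 else parent2.use_skip
    child = Genome(
        dropout_rate=child_dropout,
        filters=tuple(filters),
        depth=child_depth,
        use_skip=child_skip,
    )
    return clip_to_bounds(child, bounds)


def mutate(
    g: Genome,
    cfg: OperatorConfig,
    bounds: GenomeBounds,
    rng: np.random.Generator,
    return_events: bool = False,
):
    """Randomly perturb a genome.

    With probability ``cfg.mutation_prob`` the dropout rate gains a uniform
    delta on ``[-dropout_delta_bound, +dropout_delta_bound]``; independently,
    each filter count (same per-event probability) gains a uniform delta on
    ``[-filter_delta_bound, +filter_delta_bound]`` rounded to the nearest
    integer.  The result is clipped to bounds (and optionally snapped to the
    nearest power of two when ``cfg.snap_pow2``).  Depth and skip flag are
    never mutated.

    When ``return_events`` is true, also returns the
    :class:`MutationEvents` describing every applied pre-clip delta.
    """
    events = MutationEvents(filter_deltas=[None] * len(g.filters))
    dropout = g.dropout_rate
    if rng.random() < cfg.mutation_prob:
        delta = float(rng.uniform(-cfg.dropout_delta_bound, cfg.dropout_delta_bound))
        dropout += delta
        events.dropout_delta = delta
    filters = list(g.filters)
    for i in range(len(filters)):
        if rng.random() < cfg.mutation_prob:
            delta = float(rng.uniform(-cfg.filter_delta_bound, cfg.filter_delta_bound))
            filters[i] = _round_half_up(filters[i] + delta)
            events.filter_deltas[i] = delta
    if cfg.snap_pow2:
        filters = [snap_to_pow2(f, bounds) for f in filters]
    mutated = clip_to_bounds(
        Genome(dropout_rate=dropout, filters=tuple(filters),
               depth=g.depth, use_skip=g.use_skip),
        bounds,
    )
    if return_events:
        return mutated, events
    return mutated


def adjusted_score(
    dice: float, depth: int, p: float, mode: str = "fraction"
) -> float:
    """Depth-penalized score used to rank architectures across depths.

    The default reading is the fraction ``dice / (d * p)``: strictly
    decreasing in depth at fixed Dice, strictly increasing in Dice at fixed
    depth, and only meaningful as a relative ranking (it can exceed 1).
    ``mode='linear'`` selects the alternative ``dice * (1 - d * p)``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if p <= 0:
        raise ValueError("penalty factor must be positive")
    if not 0.0 <= dice <= 1.0:
        raise ValueError("dice must be in [0, 1]")
    if mode == "fraction":
        return dice / (depth * p)
    if mode == "linear":
        return dice * (1.0 - depth * p)
    raise ValueError("mode must be 'fraction' or 'linear'")


def has_converged(avg_by_generation: Sequence[float], tol: float) -> bool:
    """Stopping rule: the last two generations' average fitness differ by
    less than ``tol``.  With fewer than two generations recorded the run
    cannot have converged."""
    if len(avg_by_generation) < 2:
        return False
    return abs(avg_by_generation[-1] - avg_by_generation[-2]) < tol
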