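"""Island-model migration between depth-indexed subpopulations.

Every few generations each subpopulation's top performer exports its
dropout rate and skip flag to every other depth.  Because filter lists are
depth-specific, a migrant's filters are regenerated for the target depth
from the catalog; its dropout is blended with the target population's mean
so migration nudges rather than overwrites.  After the exchange each
subpopulation is truncated to a small elite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    FilterCatalog,
    Genome,
    GenomeBounds,
    clip_to_bounds,
    serialize_genome,
)
from .operators import FitnessRecord, OperatorConfig, adjusted_score

__all__ = [
    "MigrationConfig",
    "MigrationEvent",
    "blend_dropout",
    "remap_filters",
    "migrate",
]


@dataclass(frozen=True)
class MigrationConfig:
    """Migration schedule and strength.

    ``migration_rate`` weights how far a target population's dropout moves
    toward the source top performer's (0 = no influence, 1 = full copy);
    ``interval`` is the number of generations between migration events;
    ``retain_after`` is the elite size each depth keeps afterwards.
    """

    migration_rate: float = 0.2
    interval: int = 3
    retain_after: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.retain_after < 1:
            raise ValueError("retain_after must be >= 1")


@dataclass(frozen=True)
class MigrationEvent:
    """One migrant transfer, for the run history log."""

    source_depth: int
    target_depth: int
    migrant: str  # canonical genome serialization


def blend_dropout(original: float, source: float, rate: float) -> float:
    """Convex blend ``(1 - rate) * original + rate * source``.

    Always lies in the closed interval between the two inputs.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("migration rate must be in [0, 1]")
    return (1.0 - rate) * original + rate * source


def remap_filters(
    source: Genome,
    target_depth: int,
    catalog: FilterCatalog,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Regenerate a migrating genome's filter list for the target depth.

    The source's filter list has the wrong length for the target
    subpopulation, so a legal list of exactly ``target_depth`` entries is
    drawn uniformly from the catalog's target-depth rows.
    """
    rows = catalog.entries_for(target_depth)
    return rows[int(rng.integers(0, len(rows)))]


def _top_record(records: Sequence[FitnessRecord]) -> FitnessRecord:
    return min(records, key=lambda r: (-r.dice, serialize_genome(r.genome)))


def migrate(
    subpops: Mapping[int, Sequence[FitnessRecord]],
    cfg: MigrationConfig,
    catalog: FilterCatalog,
    rng: np.random.Generator,
    bounds: GenomeBounds | None = None,
    op_cfg: OperatorConfig | None = None,
    events: list[MigrationEvent] | None = None,
) -> dict[int, list[FitnessRecord]]:
    """One all-to-all migration step followed by elite truncation.

    For every ordered (source, target) depth pair a migrant is built from
    the source's top performer: dropout blended against the target
    population's mean dropout, skip flag copied, filters regenerated for
    the target depth.  Migrants carry the source top's fitness as a
    provisional score (re-evaluated when next trained).  Each subpopulation
    is then truncated to ``cfg.retain_after`` members by fitness; the
    subpopulation's own top performer is always among them, so migration
    can never discard the best solution a depth has found.

    Pass ``events`` to collect a :class:`MigrationEvent` per transfer.
    """
    bounds = bounds or GenomeBounds()
    op_cfg = op_cfg or OperatorConfig()
    for depth, records in subpops.items():
        if len(records) == 0:
            raise ValueError(f"subpopulation at depth {depth} is empty")
    depths = sorted(subpops)
    tops = {d: _top_record(subpops[d]) for d in depths}
    mean_dropout = {
        d: float(np.mean([r.genome.dropout_rate for r in subpops[d]])) for d in depths
    }
    incoming: dict[int, list[FitnessRecord]] = {d: [] for d in depths}
    for source in depths:
        src = tops[source]
        for target in depths:
            if target == source:
                continue
            filters = remap_filters(src.genome, target, catalog, rng)
            dropout = blend_dropout(
                mean_dropout[target], src.genome.dropout_rate, cfg.migration_rate
            )
            migrant_genome = clip_to_bounds(
                Genome(
                    dropout_rate=dropout,
                    filters=filters,
                    depth=target,
                    use_skip=src.genome.use_skip,
                ),
                bounds,
            )
            migrant = FitnessRecord(
                genome=migrant_genome,
                dice=src.dice,
                adjusted=adjusted_score(
                    src.dice, target, op_cfg.penalty_factor, op_cfg.penalty_mode
                ),
                generation=src.generation,
                subpopulation_depth=target,
                provisional=True,
            )
            incoming[target].append(migrant)
            if events is not None:
                events.append(
                    MigrationEvent(
                        source_depth=source,
                        target_depth=target,
                        migrant=serialize_genome(migrant_genome),
                    )
                )
    updated: dict[int, list[FitnessRecord]] = {}
    for d in depths:
        local_best = tops[d]
        pool = [r for r in subpops[d] if r is not local_best] + incoming[d]
        pool.sort(key=lambda r: (-r.dice, serialize_genome(r.genome)))
        updated[d] = [local_best] + pool[: cfg.retain_after - 1]
    return updated
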