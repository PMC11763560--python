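"""Ready-made run configurations.

``full_config`` mirrors the full-scale search protocol (depths 3--6, six
genomes per depth, 30-epoch phase-1 evaluations, 300-epoch early-stopped
phase-2 refinement at Adam learning rate 1e-4, three folds).

``desk_config`` is the scaled-down counterpart meant to run end to end on
one CPU in minutes: two depths with a small-filter catalog, four genomes
per depth, three generations of 3-epoch evaluations, two refinement
rounds of 15-epoch trainings, and a larger learning rate (1e-2) so the
short trainings converge.  The desk catalog keeps the shallow levels
narrow because wide early levels dominate CPU convolution cost.
"""

from __future__ import annotations

from .evolution import GAConfig
from .genome import FilterCatalog, GenomeBounds
from .migration import MigrationConfig
from .operators import OperatorConfig
from .trainer import TrainConfig

__all__ = ["desk_config", "full_config", "desk_catalog"]


def desk_catalog() -> FilterCatalog:
    """Small-filter catalog for CPU-scale runs (depths 3 and 4)."""
    return FilterCatalog(
        entries={
            3: ((8, 16, 32), (8, 16, 64), (8, 32, 64), (8, 32, 32)),
            4: ((8, 16, 32, 64), (8, 16, 16, 32), (8, 32, 32, 64), (8, 16, 64, 64)),
        }
    )


def desk_config(seed: int = 0) -> GAConfig:
    """Desk-scale two-phase search: minutes on one CPU, 64x64 inputs."""
    return GAConfig(
        bounds=GenomeBounds(depth_set=frozenset({3, 4})),
        catalog=desk_catalog(),
        operators=OperatorConfig(),
        migration=MigrationConfig(),
        train=TrainConfig(learning_rate=1e-2, batch_size=8, early_stop_patience=10),
        population_per_depth=4,
        max_generations=3,
        phase1_epochs=3,
        phase2_epochs=15,
        phase2_generations=2,
        folds=3,
        split_fraction=0.8,
        seed=seed,
        parallel_workers=1,
    )


def full_config(seed: int = 0) -> GAConfig:
    """The full-scale protocol (hours of compute; defaults throughout)."""
    return GAConfig(seed=seed)
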