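"""Phase-1/phase-2 orchestration tested with deterministic stub evaluators
(no network training involved)."""

import numpy as np
import pytest

from evoseg.evolution import (
    EvolutionarySearch,
    GAConfig,
    evaluate_fitness_parallel,
    genome_seed,
    run_phase1,
    run_phase2,
)
from evoseg.genome import (
    Genome,
    GenomeBounds,
    default_catalog,
    serialize_genome,
    validate_genome,
)
from evoseg.migration import MigrationConfig
from evoseg.operators import OperatorConfig, adjusted_score
from evoseg.phantom import PhantomConfig, generate_arrays
from evoseg.presets import desk_catalog

_CATALOG_ROWS = {
    row for rows in default_catalog().entries.values() for row in rows
}


def stub_fitness(genome, dataset, epochs, seed):
    """Deterministic fitness: 1 exactly on catalog rows, decaying with the
    L1 distance to the nearest catalog row of the genome's depth."""
    rows = [r for r in _CATALOG_ROWS if len(r) == genome.depth]
    if not rows:
        return 0.1
    dist = min(
        sum(abs(a - b) for a, b in zip(genome.filters, row)) for row in rows
    )
    return float(np.exp(-0.01 * dist))


def noisy_stub_fitness(genome, dataset, epochs, seed):
    """Deterministic but genome-dependent pseudo-random fitness (stable
    across processes)."""
    import hashlib

    digest = hashlib.md5(serialize_genome(genome).encode()).digest()
    return 0.3 + 0.6 * (digest[0] * 256 + digest[1]) / 65536.0


def failing_evaluator(genome, dataset, epochs, seed):
    raise RuntimeError("synthetic evaluator crash")


_FLAKY_CALLS: dict[str, int] = {}


def flaky_evaluator(genome, dataset, epochs, seed):
    key = serialize_genome(genome)
    _FLAKY_CALLS[key] = _FLAKY_CALLS.get(key, 0) + 1
    if _FLAKY_CALLS[key] == 1:
        raise RuntimeError("transient failure")
    return 0.5


@pytest.fixture
def tiny_data():
    return generate_arrays(PhantomConfig(height=16, width=16, seed=0), 6)


def small_config(**overrides):
    defaults = dict(
        bounds=GenomeBounds(depth_set=frozenset({3, 4})),
        catalog=desk_catalog(),
        operators=OperatorConfig(convergence_tol=1e-12),
        migration=MigrationConfig(),
        population_per_depth=4,
        max_generations=2,
        phase1_epochs=2,
        phase2_epochs=2,
        phase2_generations=2,
        folds=3,
        seed=7,
    )
    defaults.update(overrides)
    return GAConfig(**defaults)


class TestEvaluateFitnessParallel:
    def test_order_preserved_with_distinct_scores(self, tiny_data):
        genomes = [Genome(0.0, (8, 16, 32 + 8 * i), 3, True) for i in range(5)]
        records = evaluate_fitness_parallel(
            genomes, tiny_data, 1, 1, 0, noisy_stub_fitness
        )
        assert len(records) == 5
        assert [r.genome for r in records] == genomes

    def test_worker_count_does_not_change_results(self, tiny_data):
        genomes = [Genome(0.0, (8, 16, 32 + 8 * i), 3, True) for i in range(4)]
        one = evaluate_fitness_parallel(
            genomes, tiny_data, 1, 1, 0, noisy_stub_fitness
        )
        four = evaluate_fitness_parallel(
            genomes, tiny_data, 1, 4, 0, noisy_stub_fitness
        )
        assert [(r.dice, r.adjusted) for r in one] == [
            (r.dice, r.adjusted) for r in four
        ]

    def test_failure_names_the_genome(self, tiny_data):
        g = Genome(0.25, (8, 16, 32), 3, True)
        with pytest.raises(RuntimeError, match="8,16,32"):
            evaluate_fitness_parallel([g], tiny_data, 1, 1, 0, failing_evaluator)

    def test_transient_failure_retried_once(self, tiny_data):
        _FLAKY_CALLS.clear()
        g = Genome(0.25, (8, 16, 32), 3, True)
        records = evaluate_fitness_parallel(
            [g], tiny_data, 1, 1, 0, flaky_evaluator
        )
        assert records[0].dice == 0.5
        assert _FLAKY_CALLS[serialize_genome(g)] == 2

    def test_per_genome_seeds_are_stable_and_bounded(self):
        g = Genome(0.25, (8, 16, 32), 3, True)
        s = genome_seed(123, g)
        assert s == genome_seed(123, g)
        assert 0 <= s < 2**31
        assert s != genome_seed(124, g)


class TestPhase1:
    def test_structural_contract(self, tiny_data):
        cfg = small_config()
        history = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        assert 1 <= len(history.generations) <= 2
        for gen in history.generations:
            assert set(gen.best_by_depth) == {3, 4}
            assert set(gen.avg_by_depth) == {3, 4}
        assert history.overall_winner is not None
        assert history.overall_winner.adjusted == max(
            r.adjusted for r in history.evaluations
        )

    def test_infinite_tolerance_stops_at_second_generation(self, tiny_data):
        cfg = small_config(
            operators=OperatorConfig(convergence_tol=np.inf), max_generations=5
        )
        history = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        assert len(history.generations) == 2

    def test_seeded_rerun_is_identical(self, tiny_data):
        cfg = small_config()
        h1 = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        h2 = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        assert [g.avg_overall for g in h1.generations] == [
            g.avg_overall for g in h2.generations
        ]
        assert h1.overall_winner.genome == h2.overall_winner.genome

    def test_every_evaluated_genome_is_valid(self, tiny_data):
        cfg = small_config(max_generations=4, migration=MigrationConfig(interval=2))
        history = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        for rec in history.evaluations:
            assert validate_genome(rec.genome, cfg.bounds) == []

    def test_per_depth_best_never_regresses(self, tiny_data):
        cfg = small_config(
            operators=OperatorConfig(convergence_tol=1e-15),
            max_generations=5,
            migration=MigrationConfig(interval=2),
        )
        history = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        for depth in (3, 4):
            bests = [g.best_by_depth[depth].adjusted for g in history.generations]
            assert all(b >= a - 1e-12 for a, b in zip(bests, bests[1:]))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            run_phase1(
                small_config(),
                generate_arrays(PhantomConfig(seed=0), 1).subset([]),
                noisy_stub_fitness,
            )

    def test_winner_matches_brute_force_over_catalog(self, tiny_data):
        """With fitness peaking exactly on catalog rows, the search winner
        attains the brute-force argmax of the adjusted score."""
        cfg = GAConfig(
            bounds=GenomeBounds(depth_set=frozenset({3, 4, 5, 6})),
            catalog=default_catalog(),
            operators=OperatorConfig(convergence_tol=1e-15),
            population_per_depth=7,  # covers the largest catalog row set
            max_generations=3,
            phase1_epochs=1,
            seed=3,
        )
        history = run_phase1(cfg, tiny_data, stub_fitness)
        oracle_best = max(
            adjusted_score(
                stub_fitness(Genome(0.1, row, depth, True), None, 1, 0),
                depth,
                cfg.operators.penalty_factor,
            )
            for depth, rows in cfg.catalog.entries.items()
            for row in rows
        )
        winner = history.overall_winner
        assert winner.adjusted == pytest.approx(oracle_best, abs=1e-12)
        assert winner.genome.depth == 3  # the depth penalty favors shallow
        assert winner.genome.filters in cfg.catalog.entries_for(3)

    def test_migration_events_recorded_on_schedule(self, tiny_data):
        cfg = small_config(
            max_generations=4,
            operators=OperatorConfig(convergence_tol=1e-15),
            migration=MigrationConfig(interval=2),
        )
        history = run_phase1(cfg, tiny_data, noisy_stub_fitness)
        by_gen = {g.generation: g.migration_events for g in history.generations}
        assert len(by_gen[2]) == 2  # two depths, one ordered pair each way
        assert by_gen[1] == [] and by_gen[3] == []


class TestPhase2:
    def test_fold_count_and_elitism(self, tiny_data):
        cfg = small_config()
        winner = Genome(0.2, (8, 16, 32), 3, True)
        baseline = noisy_stub_fitness(winner, tiny_data, 2, 0)

        def cv_scorer(genome, dataset, k, seed):
            return [noisy_stub_fitness(genome, dataset, 2, seed)] * k

        final, scores, mean, std = run_phase2(
            winner, cfg, tiny_data, noisy_stub_fitness, cv_scorer=cv_scorer
        )
        assert len(scores) == cfg.folds == 3
        assert std == pytest.approx(0.0, abs=1e-12)
        # elitism: the lineage never accepts a worse genome
        assert noisy_stub_fitness(final, tiny_data, 2, 0) >= baseline

    def test_invalid_winner_rejected(self, tiny_data):
        bad = Genome(0.9, (8, 16, 32), 3, True)
        with pytest.raises(ValueError, match="invalid"):
            run_phase2(bad, small_config(), tiny_data, noisy_stub_fitness)


class TestEvolutionarySearchEstimator:
    def test_fit_exposes_history_and_winner(self, tiny_data):
        est = EvolutionarySearch(
            config=small_config(), refine=False, evaluator=noisy_stub_fitness
        )
        est.fit(tiny_data.images, tiny_data.masks)
        assert est.best_genome_ == est.history_.overall_winner.genome
        assert not hasattr(est, "final_genome_")

    def test_sklearn_get_params(self):
        est = EvolutionarySearch(refine=False)
        assert est.get_params()["refine"] is False


def test_gaconfig_yaml_round_trip(tmp_path):
    cfg = small_config()
    path = tmp_path / "run.yaml"
    cfg.to_yaml(path)
    loaded = GAConfig.from_yaml(path)
    assert loaded == cfg


def test_gaconfig_validation():
    with pytest.raises(ValueError):
        GAConfig(population_per_depth=1)
    with pytest.raises(ValueError):
        GAConfig(split_fraction=1.2)
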