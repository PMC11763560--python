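import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoseg.genome import Genome, GenomeBounds, serialize_genome, validate_genome
from evoseg.operators import (
    FitnessRecord,
    OperatorConfig,
    adjusted_score,
    average_fitness,
    crossover,
    dice_coefficient,
    has_converged,
    mutate,
    select_top_half,
)


def brute_force_dice(a, b, smooth=1e-6):
    """Pixel-loop oracle for the Dice coefficient."""
    inter = total = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            inter += int(a[i, j] and b[i, j])
            total += int(a[i, j]) + int(b[i, j])
    return 2.0 * inter / (total + smooth)


def record(genome, dice, gen=1, p=0.1):
    return FitnessRecord(
        genome=genome,
        dice=dice,
        adjusted=adjusted_score(dice, genome.depth, p),
        generation=gen,
        subpopulation_depth=genome.depth,
    )


def make_genome(i, depth=3):
    return Genome(0.01 * (i % 40), (8 + i, 16 + i, 32 + i), depth, i % 2 == 0)


class TestDice:
    def test_identical_masks_score_one(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m.flat[:10] = 1
        assert dice_coefficient(m, m) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        b = np.zeros((5, 5), dtype=np.uint8)
        a.flat[:10] = 1
        b.flat[10:20] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a.flat[:4] = 1
        b.flat[2:6] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.5, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            dice_coefficient(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_matches_pixel_loop_oracle_and_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = (rng.random((16, 16)) > 0.6).astype(np.uint8)
            b = (rng.random((16, 16)) > 0.6).astype(np.uint8)
            d = dice_coefficient(a, b)
            assert d == pytest.approx(brute_force_dice(a, b), abs=1e-12)
            assert d == dice_coefficient(b, a)


class TestAverageFitness:
    def test_mean(self):
        assert average_fitness([0.8, 0.6]) == pytest.approx(0.7, abs=1e-12)

    def test_singleton_identity(self):
        assert average_fitness([0.37]) == pytest.approx(0.37)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            average_fitness([])


class TestSelection:
    def test_top_half_retained_and_winner(self):
        pop = [record(make_genome(i), d) for i, d in enumerate([0.9, 0.8, 0.7, 0.6])]
        retained, winner = select_top_half(pop)
        assert [r.dice for r in retained] == [0.9, 0.8]
        assert winner.dice == 0.9

    def test_single_genome_population(self):
        pop = [record(make_genome(0), 0.5)]
        retained, winner = select_top_half(pop)
        assert retained == pop and winner is pop[0]

    def test_odd_population_keeps_ceiling(self):
        pop = [record(make_genome(i), 0.1 * i) for i in range(5)]
        retained, _ = select_top_half(pop)
        assert len(retained) == 3

    def test_tie_break_is_deterministic(self):
        g1, g2 = make_genome(1), make_genome(2)
        low = [record(make_genome(5), 0.3), record(make_genome(6), 0.2)]
        pop = [record(g1, 0.8), record(g2, 0.8)] + low
        retained, winner = select_top_half(pop)
        assert {r.genome for r in retained} == {g1, g2}
        expected = min(
            (serialize_genome(g1), g1), (serialize_genome(g2), g2)
        )[1]
        assert winner.genome == expected
        # order of the input must not matter
        _, winner2 = select_top_half(pop[::-1])
        assert winner2.genome == expected

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            select_top_half([])

    def test_retained_dominate_discarded(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            pop = [
                record(make_genome(i), float(rng.random()))
                for i in range(int(rng.integers(1, 12)))
            ]
            retained, _ = select_top_half(pop)
            discarded = [r for r in pop if r not in retained]
            if discarded:
                assert min(r.dice for r in retained) >= max(
                    r.dice for r in discarded
                )


class TestCrossover:
    def test_dropout_and_filters_averaged(self, bounds, rng):
        p1 = Genome(0.2, (16, 32, 64, 128), 4, True)
        p2 = Genome(0.3, (64, 128, 256, 512), 4, False)
        child = crossover(p1, p2, rng, bounds)
        assert child.dropout_rate == pytest.approx(0.25, abs=1e-12)
        assert child.filters == (40, 80, 160, 320)
        assert child.depth == 4
        assert child.use_skip in (True, False)

    def test_identical_parents_fixed_point(self, bounds, rng, winner_genome):
        child = crossover(winner_genome, winner_genome, rng, bounds)
        assert child == winner_genome

    def test_mixed_depth_rejected_by_default(self, bounds, rng):
        p1 = Genome(0.1, (8, 16, 32), 3, True)
        p2 = Genome(0.1, (8, 16, 32, 64), 4, True)
        with pytest.raises(ValueError, match="depth"):
            crossover(p1, p2, rng, bounds)

    def test_mixed_depth_alignment_mode(self, bounds, rng):
        p1 = Genome(0.1, (8, 16, 32), 3, True)
        p2 = Genome(0.3, (16, 32, 64, 128), 4, True)
        child = crossover(p1, p2, rng, bounds, cross_depth="align")
        assert child.depth == 4  # round-half-up of 3.5
        assert child.filters == (12, 24, 48, 128)  # deep tail from parent2
        assert child.dropout_rate == pytest.approx(0.2)

    @settings(derandomize=True, max_examples=60)
    @given(
        d1=st.floats(0, 0.5),
        d2=st.floats(0, 0.5),
        f1=st.lists(st.integers(8, 1024), min_size=3, max_size=3),
        f2=st.lists(st.integers(8, 1024), min_size=3, max_size=3),
        seed=st.integers(0, 2**16),
    )
    def test_child_in_convex_hull_of_parents(self, d1, d2, f1, f2, seed):
        bounds = GenomeBounds()
        p1 = Genome(d1, tuple(f1), 3, True)
        p2 = Genome(d2, tuple(f2), 3, False)
        child = crossover(p1, p2, np.random.default_rng(seed), bounds)
        assert min(d1, d2) <= child.dropout_rate <= max(d1, d2)
        for c, a, b in zip(child.filters, f1, f2):
            assert min(a, b) <= c <= max(a, b) or abs(c - (a + b) / 2) <= 0.5
        assert child.use_skip in (p1.use_skip, p2.use_skip)


class TestMutate:
    def test_quiet_seed_leaves_genome_unchanged(self, bounds):
        g = Genome(0.25, (16, 32, 64), 3, True)
        cfg = OperatorConfig()
        # seed chosen so none of the four 10% coins fire
        rng = np.random.default_rng(1)
        assert rng.random(4).min() >= cfg.mutation_prob  # coin draws all tails
        out = mutate(g, cfg, bounds, np.random.default_rng(1))
        assert out == g

    def test_lower_bound_clip(self, bounds):
        # with near-certain mutation, a filter at f_min never drops below it
        cfg = OperatorConfig(mutation_prob=0.999)
        g = Genome(0.0, (8, 8, 8), 3, False)
        for seed in range(50):
            out = mutate(g, cfg, bounds, np.random.default_rng(seed))
            assert all(f >= bounds.f_min for f in out.filters)
            assert out.dropout_rate >= 0.0

    def test_depth_and_skip_never_mutated(self, bounds):
        cfg = OperatorConfig(mutation_prob=0.999)
        g = Genome(0.3, (16, 32, 64, 128), 4, True)
        for seed in range(20):
            out = mutate(g, cfg, bounds, np.random.default_rng(seed))
            assert out.depth == 4 and out.use_skip is True

    def test_applied_deltas_respect_uniform_bounds(self, bounds):
        cfg = OperatorConfig()
        g = Genome(0.25, (100, 200, 300), 3, True)
        for seed in range(2000):
            _, events = mutate(
                g, cfg, bounds, np.random.default_rng(seed), return_events=True
            )
            if events.dropout_delta is not None:
                assert abs(events.dropout_delta) <= cfg.dropout_delta_bound
            for delta in events.filter_deltas:
                if delta is not None:
                    assert abs(delta) <= cfg.filter_delta_bound

    def test_outputs_always_within_bounds(self, bounds):
        cfg = OperatorConfig(mutation_prob=0.5)
        g = Genome(0.49, (8, 1020, 512), 3, True)
        for seed in range(200):
            out = mutate(g, cfg, bounds, np.random.default_rng(seed))
            violations = [
                v for v in validate_genome(out, bounds) if "depth" not in v
            ]
            assert violations == []

    def test_snap_pow2_mode(self, bounds):
        cfg = OperatorConfig(mutation_prob=0.999, snap_pow2=True)
        g = Genome(0.1, (16, 32, 64), 3, True)
        for seed in range(30):
            out = mutate(g, cfg, bounds, np.random.default_rng(seed))
            assert all(f & (f - 1) == 0 for f in out.filters)


class TestAdjustedScore:
    def test_literal_fraction_reading(self):
        assert adjusted_score(0.8, 4, 0.1) == pytest.approx(2.0, abs=1e-12)

    def test_depth_increase_shrinks_score(self):
        s4 = adjusted_score(0.77, 4, 0.1)
        s5 = adjusted_score(0.77, 5, 0.1)
        assert s5 == pytest.approx(s4 * 4 / 5, abs=1e-12)

    def test_zero_dice_scores_zero(self):
        assert adjusted_score(0.0, 6, 0.1) == 0.0

    def test_linear_mode(self):
        assert adjusted_score(0.8, 4, 0.1, mode="linear") == pytest.approx(
            0.8 * 0.6, abs=1e-12
        )

    @pytest.mark.parametrize("depth, p", [(0, 0.1), (-1, 0.1), (3, 0.0), (3, -2)])
    def test_invalid_arguments_raise(self, depth, p):
        with pytest.raises(ValueError):
            adjusted_score(0.5, depth, p)

    def test_shallower_always_scores_higher_at_equal_dice(self):
        for dice in (0.2, 0.5, 0.99):
            scores = [adjusted_score(dice, d, 0.1) for d in (3, 4, 5, 6)]
            assert all(a > b for a, b in zip(scores, scores[1:]))


class TestConvergence:
    def test_small_change_converges(self):
        assert has_converged([0.8495, 0.8500], 1e-3) is True

    def test_large_change_does_not(self):
        assert has_converged([0.80, 0.85], 1e-3) is False

    def test_single_generation_cannot_converge(self):
        assert has_converged([0.8], 1e-3) is False

    def test_only_last_two_generations_matter(self):
        assert has_converged([0.1, 0.9, 0.9001], 1e-3) is True
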