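"""Unit and property tests for the lion optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paddypest.loa import (
    EvaluationError,
    LOAConfig,
    decode_prey_flight,
    equilibrium_step,
    hunting_step,
    initialize_population,
    mating_step,
    migration_step,
    defense_step,
    optimize,
    orthonormal_pair,
    tournament_size,
)
from paddypest.loa.population import FEMALE, MALE, NOMAD, RESIDENT


def sphere(x):
    return float(np.sum(x * x))


class TestConfig:
    def test_default_parameters_match_study_tuning(self):
        config = LOAConfig(lower_bounds=np.zeros(2), upper_bounds=np.ones(2))
        assert config.population_size == 500
        assert config.nomad_ratio == 0.2
        assert config.num_prides == 5
        assert config.female_ratio == 0.8
        assert config.roaming_fraction == 0.2
        assert config.mating_fraction == 0.3
        assert config.mutation_rate == 0.2
        assert config.immigration_fraction == 0.4

    @pytest.mark.parametrize("field,value", [
        ("nomad_ratio", 0.0), ("nomad_ratio", 1.0),
        ("female_ratio", 1.5), ("num_prides", 0),
        ("mutation_rate", -0.1),
    ])
    def test_invalid_fractions_rejected(self, field, value):
        with pytest.raises(ValueError):
            LOAConfig(lower_bounds=np.zeros(2), upper_bounds=np.ones(2),
                      **{field: value})

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            LOAConfig(lower_bounds=np.ones(2), upper_bounds=np.zeros(2))


class TestInitialization:
    def test_census_split_forced_by_study_parameters(self, sphere_objective):
        config = LOAConfig(lower_bounds=np.zeros(2), upper_bounds=np.ones(2),
                           population_size=500, seed=0)
        pop = initialize_population(sphere_objective, config)
        assert len(pop.nomads()) == 100
        sizes = [len(pop.members(p)) for p in range(5)]
        assert sum(sizes) == 400
        assert all(size == 80 for size in sizes)

    def test_pride_of_ten_gets_eight_females(self, sphere_objective):
        # 50 residents in 5 prides of 10 at female_ratio 0.8
        config = LOAConfig(lower_bounds=np.zeros(2), upper_bounds=np.ones(2),
                           population_size=63, nomad_ratio=0.2, num_prides=5,
                           seed=1)
        pop = initialize_population(sphere_objective, config)
        for p in range(5):
            assert len(pop.pride_females(p)) == 8
            assert len(pop.pride_males(p)) == 2

    def test_positions_within_bounds_and_best_initialized(self, small_config):
        pop = initialize_population(sphere, small_config(dim=4))
        for lion in pop.lions.values():
            assert (lion.position >= -5.0).all() and (lion.position <= 5.0).all()
            assert lion.best_fitness == lion.fitness
            np.testing.assert_array_equal(lion.best_position, lion.position)

    def test_nomads_have_no_pride(self, small_config):
        pop = initialize_population(sphere, small_config())
        assert all(l.pride_id is None for l in pop.nomads())

    def test_non_finite_objective_flagged_with_point(self, small_config):
        with pytest.raises(EvaluationError) as err:
            initialize_population(lambda x: float("nan"), small_config())
        assert err.value.point is not None


class TestTournament:
    @pytest.mark.parametrize("k,expected", [(0, 2), (1, 2), (2, 2), (3, 2),
                                            (4, 2), (5, 3), (6, 3), (7, 4)])
    def test_size_rule(self, k, expected):
        assert tournament_size(k) == expected

    def test_size_rule_closed_form_up_to_twenty(self):
        for k in range(21):
            assert tournament_size(k) == max(2, math.ceil(k / 2))


class TestMoveGeometry:
    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_orthonormal_pair_contract(self, seed):
        rng = np.random.default_rng(seed)
        start = rng.normal(size=5)
        target = rng.normal(size=5)
        d, r1, r2 = orthonormal_pair(start, target, rng)
        assert d == pytest.approx(np.linalg.norm(target - start))
        assert abs(np.dot(r1, r2)) < 1e-9
        assert np.linalg.norm(r2) == pytest.approx(1.0, abs=1e-9)

    def test_zero_distance_yields_no_direction(self):
        rng = np.random.default_rng(0)
        point = np.ones(3)
        d, r1, r2 = orthonormal_pair(point, point.copy(), rng)
        assert d == 0.0 and not r1.any()

    def test_one_dimensional_has_no_orthogonal(self):
        rng = np.random.default_rng(0)
        d, r1, r2 = orthonormal_pair(np.array([0.0]), np.array([2.0]), rng)
        assert d == 2.0 and r2[0] == 0.0


class TestHunting:
    def test_prey_starts_at_hunter_centroid(self, small_config):
        config = small_config(dim=1, population_size=8, num_prides=1,
                              nomad_ratio=0.25, hunter_fraction=0.99)
        # constant objective: no attack improves, so the prey never flees
        pop = initialize_population(lambda x: 1.0, config)
        females = pop.pride_females(0)
        centroid = np.mean([f.position for f in females], axis=0)
        rng = np.random.default_rng(0)
        hunters, state = hunting_step(pop, 0, config, rng)
        assert len(hunters) == len(females)
        np.testing.assert_allclose(state.prey, centroid)
        assert state.improvement == 0.0

    def test_wing_jump_support_contains_draws(self):
        # 1-D: PREY=2, Hunter=5 -> jump always lands in [-1, 2]
        from paddypest.loa.operators import _rand_between

        rng = np.random.default_rng(42)
        prey, hunter = np.array([2.0]), np.array([5.0])
        opposite = 2.0 * prey - hunter
        draws = np.array([_rand_between(opposite, prey, rng)[0]
                          for _ in range(10_000)])
        assert draws.min() >= -1.0 and draws.max() <= 2.0

    def test_prey_flight_scales_with_improvement(self):
        rng = np.random.default_rng(0)
        prey = np.array([2.0])
        hunter = np.array([1.0])
        # full improvement: PI clamps to 1
        moved = decode_prey_flight(prey, hunter, f_old=10.0, f_new=0.0, rng=rng)
        assert moved[0] >= prey[0]  # flees away from the hunter
        # no improvement: PI = 0, prey stays
        stay = decode_prey_flight(prey, hunter, f_old=1.0, f_new=1.0,
                                  rng=np.random.default_rng(0))
        np.testing.assert_array_equal(stay, prey)


class TestMating:
    def test_midpoint_with_beta_half_single_male(self, small_config):
        from paddypest.loa.operators import _crossover
        from paddypest.loa.population import Lion

        mother = Lion(0, np.array([0.0, 2.0]), 1.0, np.array([0.0, 2.0]), 1.0,
                      FEMALE, RESIDENT, 0)
        father = Lion(1, np.array([2.0, 0.0]), 1.0, np.array([2.0, 0.0]), 1.0,
                      MALE, RESIDENT, 0)
        off1, off2 = _crossover(mother, [father], np.array([1]), beta=0.5)
        np.testing.assert_allclose(off1, [1.0, 1.0])
        np.testing.assert_allclose(off2, [1.0, 1.0])

    def test_zero_mutation_gives_exact_linear_combinations(self, small_config):
        config = small_config(dim=3, population_size=12, num_prides=1,
                              mutation_rate=0.0, mating_fraction=0.9)
        pop = initialize_population(sphere, config)
        rng = np.random.default_rng(5)
        events = mating_step(pop, config, rng, 0)
        assert events
        for event in events:
            mother = pop.lions[event.mother_id]
            males = pop.pride_males(0)
            # offspring are exact convex combinations => inside parent box
            for cub in event.offspring:
                assert cub.gender in (FEMALE, MALE)
        genders = {c.gender for c in events[0].offspring}
        assert genders == {FEMALE, MALE}

    def test_full_mutation_draws_uniform_in_bounds(self):
        # park every parent at the origin of [0,1]^4: the unmutated cub
        # is exactly 0, so all nonzero genes come from mutation and must
        # be uniform on [0,1]
        config = LOAConfig(lower_bounds=np.zeros(4), upper_bounds=np.ones(4),
                           population_size=16, num_prides=1, nomad_ratio=0.2,
                           mutation_rate=1.0, mating_fraction=0.9, seed=3)
        pop = initialize_population(lambda x: 1.0, config)
        for lion in pop.lions.values():
            lion.position = np.zeros(4)
        rng = np.random.default_rng(9)
        genes = []
        for _ in range(500):
            for event in mating_step(pop, config, rng, 0):
                for cub in event.offspring:
                    genes.extend(cub.position[cub.position > 0.0])
                    pop.remove(cub.id)
        genes = np.asarray(genes)
        assert genes.size > 5_000
        assert genes.mean() == pytest.approx(0.5, abs=0.02)
        assert genes.min() >= 0.0 and genes.max() <= 1.0

    def test_no_males_skips_mating(self, small_config):
        config = small_config(dim=2, population_size=12, num_prides=1)
        pop = initialize_population(sphere, config)
        for male in pop.pride_males(0):
            male.role = NOMAD
            male.pride_id = None
        events = mating_step(pop, config, np.random.default_rng(0), 0)
        assert events == []


class TestDefenseMigrationEquilibrium:
    def test_worst_male_evicted_at_quota_one(self, small_config):
        config = small_config(dim=2, population_size=12, num_prides=1, seed=2)
        pop = initialize_population(sphere, config)
        pop.pride_male_quota[0] = 1
        males = pop.pride_males(0)
        assert len(males) >= 2
        worst = max(males, key=lambda l: (l.fitness, l.id))
        defense_step(pop, np.random.default_rng(3))
        assert len(pop.pride_males(0)) <= 1
        assert pop.lions[worst.id].role == NOMAD

    def test_nomad_takeover_requires_better_fitness(self, small_config):
        config = small_config(dim=2, population_size=12, num_prides=1, seed=2)
        pop = initialize_population(sphere, config)
        nomad_males = pop.nomads(MALE)
        if not nomad_males:
            pytest.skip("seeded census produced no nomad males")
        nomad = nomad_males[0]
        weakest = max(pop.pride_males(0), key=lambda l: (l.fitness, l.id))
        nomad.fitness = weakest.fitness + 1.0  # strictly worse: never swaps
        defense_step(pop, np.random.default_rng(0))
        assert pop.lions[nomad.id].role == NOMAD

    def test_migration_conserves_total_count(self, small_config):
        config = small_config(dim=2, population_size=30, num_prides=3)
        pop = initialize_population(sphere, config)
        before = len(pop.lions)
        migration_step(pop, config, np.random.default_rng(0))
        assert len(pop.lions) == before

    def test_migration_refills_with_fittest_nomad_females(self, small_config):
        config = small_config(dim=2, population_size=30, num_prides=3)
        pop = initialize_population(sphere, config)
        migration_step(pop, config, np.random.default_rng(0))
        for p in range(3):
            assert len(pop.pride_females(p)) == pop.pride_female_quota[p]
        # any remaining nomad female is no fitter than the refilled ones
        # would only hold for the last pride processed; check quotas only

    def test_equilibrium_trims_worst_nomads(self, small_config):
        config = small_config(dim=2, population_size=30, num_prides=3)
        pop = initialize_population(sphere, config)
        quota_f, quota_m = pop.nomad_female_max, pop.nomad_male_max
        # inflate the nomad pool with poor solutions
        for _ in range(5):
            pop.spawn(np.full(2, 5.0), FEMALE, NOMAD, None)
            pop.spawn(np.full(2, 5.0), MALE, NOMAD, None)
        equilibrium_step(pop)
        assert len(pop.nomads(FEMALE)) == quota_f
        assert len(pop.nomads(MALE)) == quota_m

    def test_equilibrium_keeps_the_best_nomad(self, small_config):
        config = small_config(dim=2, population_size=30, num_prides=3)
        pop = initialize_population(sphere, config)
        star = pop.spawn(np.zeros(2), MALE, NOMAD, None)  # fitness 0: the best
        for _ in range(4):
            pop.spawn(np.full(2, 4.0), MALE, NOMAD, None)
        equilibrium_step(pop)
        assert star.id in pop.lions


class TestOptimize:
    def test_constant_objective_stops_at_patience(self, small_config):
        config = small_config(max_iterations=100, patience=5)
        result = optimize(lambda x: 3.5, config)
        assert result.best_fitness == 3.5
        assert result.n_iterations == 5

    def test_trace_best_is_non_increasing(self, small_config):
        result = optimize(sphere, small_config(max_iterations=30))
        diffs = result.trace["best_fitness"].diff().dropna()
        assert (diffs <= 1e-12).all()

    def test_census_constant_every_iteration(self, small_config):
        config = small_config(population_size=40, num_prides=4,
                              max_iterations=25)
        result = optimize(sphere, config)
        assert (result.trace["total"] == 40).all()

    def test_identical_seed_gives_bit_identical_trace(self, small_config):
        config = small_config(max_iterations=15, seed=11)
        first = optimize(sphere, config)
        second = optimize(sphere, config)
        assert first.trace.equals(second.trace)
        np.testing.assert_array_equal(first.best_position, second.best_position)

    def test_positions_and_quotas_respected_after_run(self, small_config):
        config = small_config(dim=3, population_size=40, num_prides=4,
                              max_iterations=20)
        rng = np.random.default_rng(config.seed)
        pop = initialize_population(sphere, config, rng)
        from paddypest.loa import operators as ops

        for _ in range(5):
            pop.reset_success_flags()
            for p in range(pop.num_prides):
                hunters, _ = ops.hunting_step(pop, p, config, rng)
                ops.safe_place_step(pop, p, config, rng, hunters)
                ops.roaming_step(pop, p, config, rng)
                ops.mating_step(pop, config, rng, p)
            ops.mating_step(pop, config, rng, None)
            ops.defense_step(pop, rng)
            ops.migration_step(pop, config, rng)
            ops.equilibrium_step(pop)
            pop.success_counts = pop.collect_success_counts()
            assert len(pop.lions) == 40
            for p in range(pop.num_prides):
                assert len(pop.pride_females(p)) == pop.pride_female_quota[p]
                assert len(pop.pride_males(p)) <= pop.pride_male_quota[p]
            for lion in pop.lions.values():
                assert (lion.position >= config.lower_bounds - 1e-12).all()
                assert (lion.position <= config.upper_bounds + 1e-12).all()
                assert lion.best_fitness <= lion.fitness + 1e-12

    def test_territory_entries_are_member_bests(self, small_config):
        config = small_config(population_size=30, num_prides=3)
        pop = initialize_population(sphere, config)
        for p in range(3):
            members = pop.members(p)
            for entry, member in zip(pop.territory(p), members):
                np.testing.assert_array_equal(entry.best_position,
                                              member.best_position)

    def test_roaming_never_worsens_a_male_at_the_optimum(self, small_config):
        from paddypest.loa.operators import roaming_step

        config = small_config(dim=2, population_size=12, num_prides=1, seed=4)
        pop = initialize_population(sphere, config)
        male = pop.pride_males(0)[0]
        male.position = np.zeros(2)
        male.fitness = male.best_fitness = 0.0
        male.best_position = np.zeros(2)
        roaming_step(pop, 0, config, np.random.default_rng(0))
        assert male.best_fitness == 0.0
        np.testing.assert_array_equal(male.best_position, np.zeros(2))

    def test_roaming_step_support_single_visit(self, small_config):
        # with one visit and no angular jitter, the move is collinear
        # with the chosen territory point and at most twice as far
        from paddypest.loa.operators import roaming_step

        config = small_config(dim=2, population_size=12, num_prides=1,
                              roaming_fraction=0.01, roaming_angle=0.0, seed=4)
        pop = initialize_population(sphere, config)
        # shrink everything deep inside the box so clipping never bites
        for lion in pop.lions.values():
            lion.position = lion.position / 10.0
            lion.best_position = lion.position.copy()
        for male in pop.pride_males(0):
            start = male.position.copy()
            max_d = max(np.linalg.norm(t.best_position - start)
                        for t in pop.territory(0))
            roaming_step(pop, 0, config, np.random.default_rng(1))
            step = np.linalg.norm(male.position - start)
            assert step <= 2.0 * max_d + 1e-12
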