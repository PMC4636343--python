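"""Communicative success, selection, inheritance, generation turnover."""

import random

import pytest

from coevolang.config import SimulationConfig
from coevolang.evolution import (
    Population,
    evaluate_cs,
    init_population,
    reproduce,
    run_simulation,
    sampling_grid,
    seed_meanings,
    select_parents,
    select_teacher,
)
from coevolang.experiments import converged_population, initial_population
from coevolang.memory import Agent, LexicalRule
from coevolang.semantics import SemanticSpace


class TestSeedRules:
    def test_seed_meanings_cover_all_constituents(self, space):
        covered = {c for m in seed_meanings(space) for c in m.constituents()}
        assert covered == set(range(space.n_constituents))

    def test_eight_seed_meanings_for_default_space(self, space):
        assert len(seed_meanings(space)) == 8


class TestEvaluateCS:
    def test_initial_shared_rules_give_one_eighth(self):
        """10 agents sharing 8 holistic rules over 64 meanings: every agent
        understands exactly those 8 from everyone, CS = 0.125."""
        pop, space = initial_population(seed=5)
        cs = evaluate_cs(pop, space)
        assert all(c == pytest.approx(0.125) for c in cs)

    def test_empty_lexicon_gives_zero(self, space):
        pop, sp = initial_population(seed=2)
        pop.agents[0].lexicon.clear()
        pop.agents[0]._lex_index.clear()
        cs = evaluate_cs(pop, sp)
        assert cs[0] == 0.0

    def test_disjoint_lexicons_no_understanding(self, space):
        a, b = Agent(10), Agent(10)
        m1, m2 = space.meanings[0], space.meanings[1]
        a.insert_lex(LexicalRule("aa", meaning=m1))
        b.insert_lex(LexicalRule("bb", meaning=m2))
        pop = Population([a, b])
        cs = evaluate_cs(pop, space)
        assert cs == [0.0, 0.0]

    def test_converged_population_full_understanding(self):
        pop, space = converged_population()
        cs = evaluate_cs(pop, space)
        assert all(c == pytest.approx(1.0) for c in cs)

    def test_evaluation_is_side_effect_free(self):
        pop, space = initial_population(seed=9)
        before = [a.knowledge_snapshot() for a in pop.agents]
        evaluate_cs(pop, space)
        after = [a.knowledge_snapshot() for a in pop.agents]
        assert before == after


class TestSelectParents:
    def test_half_of_adults_selected(self):
        pop, _ = initial_population(seed=1)
        idx = select_parents(pop, [0.5] * 10, False, random.Random(0))
        assert len(idx) == 5
        assert len(set(idx)) == 5

    def test_uniform_when_natural_off(self):
        pop, _ = initial_population(seed=1)
        rng = random.Random(2)
        counts = [0] * 10
        reps = 4000
        for _ in range(reps):
            for i in select_parents(pop, [0.9, 0.1] * 5, False, rng):
                counts[i] += 1
        for c in counts:
            assert abs(c / reps - 0.5) < 0.05

    def test_cs_proportional_when_natural_on(self):
        pop, _ = initial_population(seed=1)
        rng = random.Random(3)
        cs = [0.9] + [0.1] * 9
        hits = 0
        reps = 2000
        for _ in range(reps):
            hits += 0 in select_parents(pop, cs, True, rng)
        # the high-CS agent is picked far more often than a uniform 1/2
        assert hits / reps > 0.85

    def test_degenerate_mass_always_selected(self):
        pop, _ = initial_population(seed=1)
        rng = random.Random(4)
        cs = [0.0] * 9 + [0.7]
        for _ in range(100):
            assert 9 in select_parents(pop, cs, True, rng)

    def test_all_zero_cs_falls_back_to_uniform(self):
        pop, _ = initial_population(seed=1)
        idx = select_parents(pop, [0.0] * 10, True, random.Random(5))
        assert len(idx) == 5


class TestSelectTeacher:
    def test_single_adult(self):
        a = Agent(10)
        assert select_teacher([a], [1.0], True, random.Random(0)) is a

    def test_uniform_when_cultural_off(self):
        adults = [Agent(10) for _ in range(4)]
        rng = random.Random(1)
        counts = [0] * 4
        reps = 8000
        for _ in range(reps):
            counts[adults.index(
                select_teacher(adults, [0.9, 0.1, 0.1, 0.1], False, rng)
            )] += 1
        for c in counts:
            assert abs(c / reps - 0.25) < 0.03

    def test_proportional_when_cultural_on(self):
        adults = [Agent(10), Agent(10)]
        rng = random.Random(2)
        reps = 10_000
        first = sum(
            select_teacher(adults, [0.9, 0.1], True, rng) is adults[0]
            for _ in range(reps)
        )
        assert abs(first / reps - 0.9) < 0.02


class TestReproduce:
    def _cfg(self, **kw):
        return SimulationConfig(**kw)

    def test_capacity_copied_exactly_without_mutation(self):
        parent = Agent(33)
        child = reproduce(parent, self._cfg(mutation=False), random.Random(0))
        assert child.lex_capacity == 33
        assert not child.lexicon and not child.stm

    def test_mutation_statistics(self):
        cfg = self._cfg(mutation=True, mutation_rate=0.05)
        rng = random.Random(6)
        parent = Agent(30)
        deltas = [
            reproduce(parent, cfg, rng).lex_capacity - 30
            for _ in range(10_000)
        ]
        rate = sum(d != 0 for d in deltas) / len(deltas)
        assert abs(rate - 0.05) < 0.01
        assert abs(sum(deltas)) < 60  # signs balance
        assert set(deltas) <= {-1, 0, 1}

    def test_floor_respected(self):
        cfg = self._cfg(mutation=True, mutation_rate=1.0, min_capacity=5)
        rng = random.Random(7)
        parent = Agent(5)
        for _ in range(50):
            assert reproduce(parent, cfg, rng).lex_capacity >= 5


class TestRunSimulation:
    def test_zero_generations_initial_sample_only(self):
        cfg = SimulationConfig(generations=0, sampling_points=21, seed=3)
        traj = run_simulation(cfg)
        assert traj.generations == [0]
        assert traj.ur[0] == pytest.approx(0.125)

    def test_population_and_communication_bookkeeping(self):
        cfg = SimulationConfig(generations=2, sampling_points=3, seed=4,
                               capacity_sd=0.0)
        traj = run_simulation(cfg)
        assert traj.generations == [0, 1, 2]
        assert all(0.0 <= u <= 1.0 for u in traj.ur)

    def test_capacity_multiset_invariant_without_mutation(self):
        """NoChange closure: offspring copy parent capacities exactly, so the
        population's capacity multiset never changes."""
        cfg = SimulationConfig(
            generations=3, sampling_points=4, seed=5, mutation=False,
            natural_selection=False, cultural_selection=False,
            capacity_sd=5.0,
        )
        import random as _r

        from coevolang.evolution import _ForgetClock, run_generation

        master = _r.Random(5)
        rngs = [_r.Random(master.getrandbits(63)) for _ in range(4)]
        space = SemanticSpace(4, 4, 4)
        pop = init_population(cfg, space, rngs[0])
        initial = sorted(a.lex_capacity for a in pop.agents)
        clock = _ForgetClock(cfg.forget_every, cfg.forget_amount)
        for _ in range(3):
            run_generation(pop, space, cfg, rngs[1], rngs[2], rngs[3], clock)
            assert sorted(a.lex_capacity for a in pop.agents) == initial

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(generations=2, sampling_points=3, seed=11,
                               natural_selection=True, mutation=True)
        t1 = run_simulation(cfg)
        t2 = run_simulation(cfg)
        assert t1.ur == t2.ur
        assert t1.mean_capacity == t2.mean_capacity

    def test_population_size_constant(self):
        cfg = SimulationConfig(generations=2, sampling_points=3, seed=6,
                               natural_selection=True, mutation=True)
        import random as _r

        from coevolang.evolution import _ForgetClock, run_generation

        master = _r.Random(6)
        rngs = [_r.Random(master.getrandbits(63)) for _ in range(4)]
        space = SemanticSpace(4, 4, 4)
        pop = init_population(cfg, space, rngs[0])
        for _ in range(2):
            run_generation(pop, space, cfg, rngs[1], rngs[2], rngs[3],
                           _ForgetClock(10, 0.01), need_cs=True)
            assert len(pop) == 10


class TestSamplingGrid:
    @pytest.mark.parametrize(
        "generations, points, expected",
        [
            (2000, 201, 201),
            (200, 21, 21),
            (0, 21, 1),
            (10, 1, 1),
        ],
    )
    def test_grid_sizes(self, generations, points, expected):
        grid = sampling_grid(generations, points)
        assert len(grid) == expected
        assert grid[0] == 0
        if generations and points > 1:
            assert grid[-1] == generations


class TestInitPopulation:
    def test_gaussian_draw_respects_floor_and_sd_zero(self):
        cfg = SimulationConfig(initial_lex_capacity=30, capacity_sd=0.0)
        space = SemanticSpace(4, 4, 4)
        pop = init_population(cfg, space, random.Random(1))
        assert all(a.lex_capacity == 30 for a in pop.agents)
        cfg2 = SimulationConfig(initial_lex_capacity=3, capacity_sd=5.0,
                                min_capacity=1)
        pop2 = init_population(cfg2, space, random.Random(2))
        assert all(a.lex_capacity >= 1 for a in pop2.agents)
        spread = {a.lex_capacity for a in pop2.agents}
        assert len(spread) > 1

    def test_all_agents_share_identical_seed_rules(self):
        pop, space = initial_population(seed=8)
        keys = [
            sorted((r.meaning, r.utterance) for r in a.lexicon)
            for a in pop.agents
        ]
        assert all(k == keys[0] for k in keys)
        assert len(keys[0]) == 8
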