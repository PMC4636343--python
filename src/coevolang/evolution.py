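"""Generational framework: cultural transmission, selection, inheritance.

Each generation (a) the adults hold a fixed number of intra-generational
communications among themselves, (b) every agent's communicative success
(CS) is evaluated -- the fraction of all meanings it decodes, from every
other agent's productions, to exactly the meaning the producer encoded,
using linguistic knowledge only -- (c) half of the adults become parents
(CS-proportionally under natural selection, uniformly otherwise), each
producing one offspring with no linguistic knowledge that inherits the
parent's lexical-LTM capacity (mutated by +-1 step at the mutation rate when
enabled), (d) adults hold inter-generational communications with the
offspring, the teacher drawn CS-proportionally under cultural selection and
uniformly otherwise, and (e) the offspring replace their parents; the other
half of the adults persists, keeping the population size constant.

The understanding rate UR (mean CS over adults) and the mean lexical-LTM
capacity are recorded at evenly spaced sampling points.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

from .communication import (
    _choose_max,
    _production_covers,
    build_comprehension_sets,
    materialize_utterance,
    run_communication,
)
from .config import SimulationConfig
from .memory import Agent, LexicalRule, apply_forgetting
from .metrics import RunTrajectory, understanding_rate
from .semantics import Meaning, SemanticSpace, random_utterance


class Population:
    """A fixed-size group of agents plus a generation counter."""

    def __init__(self, agents: Sequence[Agent]):
        self.agents: list[Agent] = list(agents)
        self.generation_index = 0

    def __len__(self) -> int:
        return len(self.agents)

    def mean_capacity(self) -> float:
        return sum(a.lex_capacity for a in self.agents) / len(self.agents)


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------


def seed_meanings(space: SemanticSpace) -> list[Meaning]:
    """Meanings for the initial shared holistic rules.

    One meaning per predicate: single-argument predicates take the entities
    in turn as agents; double-argument predicates take rotated agent/patient
    pairs so that every entity also occurs in patient position.  Together the
    seed meanings contain every semantic constituent of the space.
    """
    e = space.n_entities
    meanings = [
        Meaning(p, k % e) for k, p in enumerate(space.single_preds)
    ]
    if space.n_double and e < 2:
        raise ValueError("double-argument meanings need at least two entities")
    meanings += [
        Meaning(p, (k + 1) % e, k % e) for k, p in enumerate(space.double_preds)
    ]
    covered = {c for m in meanings for c in m.constituents()}
    if covered != set(range(space.n_constituents)):
        raise ValueError(
            "seed meanings do not cover all semantic constituents; "
            "use at least as many predicates of each kind as entities"
        )
    return meanings


def seed_rules(
    space: SemanticSpace, rng: random.Random
) -> list[tuple[Meaning, str]]:
    """Shared holistic seed rules: seed meanings with distinct random
    utterances (shared verbatim by every agent)."""
    pairs: list[tuple[Meaning, str]] = []
    used: set[str] = set()
    for m in seed_meanings(space):
        while True:
            u = random_utterance(rng, len(m.constituents()))
            if u not in used:
                used.add(u)
                break
        pairs.append((m, u))
    return pairs


def init_population(
    cfg: SimulationConfig, space: SemanticSpace, rng: random.Random
) -> Population:
    """First generation: shared holistic rules, Gaussian capacity draw.

    Capacities are drawn from a Gaussian around the configured mean
    (``capacity_sd``; 0 gives identical capacities), rounded to the nearest
    integer and floored at ``min_capacity``.
    """
    shared = seed_rules(space, rng)
    agents = []
    for _ in range(cfg.population_size):
        if cfg.capacity_sd > 0:
            cap = round(rng.gauss(cfg.initial_lex_capacity, cfg.capacity_sd))
        else:
            cap = cfg.initial_lex_capacity
        cap = max(cfg.min_capacity, cap)
        agent = Agent(
            cap,
            stm_capacity=cfg.stm_capacity,
            syn_capacity=cfg.syn_capacity,
            cat_capacity=cfg.cat_capacity,
        )
        for meaning, utterance in shared:
            agent.insert_lex(LexicalRule(utterance, meaning=meaning))
        agents.append(agent)
    return Population(agents)


# ---------------------------------------------------------------------------
# Communicative success (Eq-3 style evaluation; side-effect free)
# ---------------------------------------------------------------------------


def _encode(agent: Agent, meaning: Meaning, space: SemanticSpace):
    """Deterministic knowledge-only production (no cue, no creation)."""
    sets = _production_covers(agent, meaning, space)
    if not sets:
        return None
    return materialize_utterance(_choose_max(sets, None), None)


def _decode(agent: Agent, utterance: str, space: SemanticSpace):
    """Deterministic knowledge-only comprehension (no cue)."""
    sets = build_comprehension_sets(agent, utterance, None, space)
    if not sets:
        return None
    return _choose_max(sets, None).meaning


def evaluate_cs(population: Population, space: SemanticSpace) -> list[float]:
    """Per-agent communicative success.

    For every ordered pair (speaker j -> listener i) counts the meanings of
    the full space that j encodes and i decodes back to the same meaning,
    normalised by ``|space| * (N - 1)``.  Evaluation uses linguistic
    knowledge only: no cues, no creation, no strength updates, no storage.
    """
    agents = population.agents
    n = len(agents)
    m_total = len(space)
    encodings: list[list[tuple[Meaning, str]]] = []
    for a in agents:
        enc = []
        for m in space.meanings:
            u = _encode(a, m, space)
            if u is not None:
                enc.append((m, u))
        encodings.append(enc)
    cs = []
    for i, listener in enumerate(agents):
        cache: dict[str, Optional[Meaning]] = {}
        count = 0
        for j in range(n):
            if j == i:
                continue
            for meaning, utterance in encodings[j]:
                got = cache.get(utterance, False)
                if got is False:
                    got = _decode(listener, utterance, space)
                    cache[utterance] = got
                if got == meaning:
                    count += 1
        value = count / (m_total * (n - 1)) if n > 1 else 0.0
        cs.append(value)
        listener.cs = value
    return cs


# ---------------------------------------------------------------------------
# Selection and reproduction
# ---------------------------------------------------------------------------


def _weighted_sample_without_replacement(
    items: list, weights: list[float], k: int, rng: random.Random
) -> list:
    """Roulette draws with successive renormalization."""
    pool = list(items)
    w = list(weights)
    chosen = []
    for _ in range(k):
        total = sum(w)
        r = rng.random() * total
        acc = 0.0
        idx = len(pool) - 1
        for i, wi in enumerate(w):
            acc += wi
            if r < acc:
                idx = i
                break
        chosen.append(pool.pop(idx))
        w.pop(idx)
    return chosen


def select_parents(
    population: Population,
    cs: Sequence[float],
    natural: bool,
    rng: random.Random,
) -> list[int]:
    """Indices of the N/2 adults chosen as parents.

    Under natural selection the draw is CS-proportional without replacement;
    otherwise uniform.  An all-zero CS vector falls back to uniform.
    """
    n = len(population)
    if n % 2:
        raise ValueError("population size must be even")
    k = n // 2
    indices = list(range(n))
    if natural and any(c > 0 for c in cs):
        return _weighted_sample_without_replacement(indices, list(cs), k, rng)
    return rng.sample(indices, k)


def select_teacher(
    adults: Sequence[Agent],
    cs: Optional[Sequence[float]],
    cultural: bool,
    rng: random.Random,
) -> Agent:
    """One adult to talk to an offspring; CS-proportional when cultural
    selection is on (uniform fallback for an all-zero CS vector)."""
    if not adults:
        raise ValueError("no adults to choose from")
    if cultural and cs is not None and any(c > 0 for c in cs):
        return _weighted_sample_without_replacement(
            list(adults), list(cs), 1, rng
        )[0]
    return adults[rng.randrange(len(adults))]


def reproduce(
    parent: Agent, cfg: SimulationConfig, rng: Optional[random.Random]
) -> Agent:
    """One offspring: empty STM/LTM, inherited (possibly mutated) capacity.

    With mutation enabled the copied capacity is increased or decreased by
    one step with equal chances at the mutation rate, floored at the
    configured minimum.
    """
    capacity = parent.lex_capacity
    if cfg.mutation and rng is not None and rng.random() < cfg.mutation_rate:
        step = cfg.mutation_step if rng.random() < 0.5 else -cfg.mutation_step
        capacity = max(cfg.min_capacity, capacity + step)
    return Agent(
        capacity,
        stm_capacity=cfg.stm_capacity,
        syn_capacity=cfg.syn_capacity,
        cat_capacity=cfg.cat_capacity,
    )


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------


class _ForgetClock:
    """Population-wide forgetting every ``every`` communications."""

    def __init__(self, every: int, amount: float):
        self.every = every
        self.amount = amount
        self.count = 0

    def tick(self, agents: Sequence[Agent]) -> None:
        self.count += 1
        if self.every > 0 and self.count % self.every == 0:
            apply_forgetting(agents, self.amount)


def run_generation(
    population: Population,
    space: SemanticSpace,
    cfg: SimulationConfig,
    comm_rng: random.Random,
    select_rng: random.Random,
    mut_rng: random.Random,
    clock: _ForgetClock,
    need_cs: bool = False,
):
    """One full generation; returns ``(cs_or_None, mean_adult_capacity)``.

    CS is evaluated only when a selection needs it or the caller asks
    (``need_cs``), which keeps selection-free baselines cheap.
    """
    adults = population.agents
    n = len(adults)
    for _ in range(cfg.intra_transmissions):
        i = comm_rng.randrange(n)
        j = comm_rng.randrange(n - 1)
        if j >= i:
            j += 1
        run_communication(adults[i], adults[j], space, cfg, comm_rng)
        clock.tick(adults)
    mean_cap = population.mean_capacity()
    cs = None
    if need_cs or cfg.natural_selection or cfg.cultural_selection:
        cs = evaluate_cs(population, space)
    parent_idx = select_parents(population, cs or [0.0] * n,
                                cfg.natural_selection, select_rng)
    offspring = [reproduce(adults[i], cfg, mut_rng) for i in parent_idx]
    everyone = adults + offspring
    for _ in range(cfg.inter_transmissions):
        teacher = select_teacher(adults, cs, cfg.cultural_selection, select_rng)
        listener = offspring[comm_rng.randrange(len(offspring))]
        run_communication(teacher, listener, space, cfg, comm_rng)
        clock.tick(everyone)
    for idx, child in zip(parent_idx, offspring):
        adults[idx] = child
    population.generation_index += 1
    return cs, mean_cap


def sampling_grid(generations: int, points: int) -> list[int]:
    """Evenly spaced sampling generations, always including generation 0."""
    if generations == 0 or points == 1:
        return [0]
    grid = sorted({round(i * generations / (points - 1)) for i in range(points)})
    return grid


def run_simulation(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> RunTrajectory:
    """A full run: initialise, iterate generations, sample UR and capacity.

    One master seed feeds four per-component child streams (initialisation,
    communication, selection, mutation) so components can be tested in
    isolation and trajectories are bit-identical for a fixed seed.
    """
    if seed is None:
        seed = cfg.seed
    master = random.Random(seed)
    init_rng, comm_rng, select_rng, mut_rng = (
        random.Random(master.getrandbits(63)) for _ in range(4)
    )
    space = SemanticSpace(cfg.n_entities, cfg.n_single, cfg.n_double)
    population = init_population(cfg, space, init_rng)
    clock = _ForgetClock(cfg.forget_every, cfg.forget_amount)
    grid = set(sampling_grid(cfg.generations, cfg.sampling_points))

    generations: list[int] = []
    ur_values: list[float] = []
    capacities: list[float] = []

    if 0 in grid:
        cs0 = evaluate_cs(population, space)
        generations.append(0)
        ur_values.append(understanding_rate(cs0))
        capacities.append(population.mean_capacity())

    for g in range(1, cfg.generations + 1):
        sample_here = g in grid
        cs, mean_cap = run_generation(
            population, space, cfg, comm_rng, select_rng, mut_rng, clock,
            need_cs=sample_here,
        )
        if sample_here:
            generations.append(g)
            ur_values.append(understanding_rate(cs))
            capacities.append(mean_cap)

    return RunTrajectory(
        generations=generations,
        ur=ur_values,
        mean_capacity=capacities,
        total_generations=cfg.generations,
        config=cfg.to_dict(),
        seed=seed,
    )
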