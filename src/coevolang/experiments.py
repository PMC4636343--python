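"""Named experiment presets, capacity sweeps, and reference fixtures.

The five named conditions are the baseline *NoChange* (no selections, no
mutation, identical initial capacities) and a 2x2 factorial over natural and
cultural selection (*NoNat_NoCul*, *Nat_NoCul*, *NoNat_Cul*, *Nat_Cul*), all
four with capacity mutation on and Gaussian initial capacities (sd 5).

Two scales are provided: ``full`` mirrors the reference experiment sizes
(50 replicates, 2000 generations, 201 sampling points) and ``desk`` is a
reduced setting (5 replicates, 200 generations, 21 points) that completes in
minutes on one CPU.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .config import SimulationConfig
from .evolution import Population, init_population, run_simulation
from .memory import Agent, Category, LexicalRule, SyntacticRule
from .metrics import (
    RunTrajectory,
    marginal_means,
    run_summary,
    trajectories_to_frame,
)
from .semantics import Meaning, SemanticSpace

#: Condition flags: (natural_selection, cultural_selection, mutation).
PRESETS: dict[str, dict] = {
    "NoChange": dict(
        natural_selection=False, cultural_selection=False, mutation=False,
        capacity_sd=0.0,
    ),
    "NoNat_NoCul": dict(
        natural_selection=False, cultural_selection=False, mutation=True,
        capacity_sd=5.0,
    ),
    "Nat_NoCul": dict(
        natural_selection=True, cultural_selection=False, mutation=True,
        capacity_sd=5.0,
    ),
    "NoNat_Cul": dict(
        natural_selection=False, cultural_selection=True, mutation=True,
        capacity_sd=5.0,
    ),
    "Nat_Cul": dict(
        natural_selection=True, cultural_selection=True, mutation=True,
        capacity_sd=5.0,
    ),
}

SCALES = {
    "full": dict(replicates=50, generations=2000, sampling_points=201),
    "desk": dict(replicates=5, generations=200, sampling_points=21),
}


@dataclass
class ExperimentPreset:
    """A named condition plus scale and overrides."""

    name: str
    scale: str = "desk"
    replicates: Optional[int] = None
    generations: Optional[int] = None
    sampling_points: Optional[int] = None
    initial_capacity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in PRESETS:
            raise ValueError(
                f"unknown preset {self.name!r}; choose from {sorted(PRESETS)}"
            )
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    def build_config(self, base: Optional[SimulationConfig] = None
                     ) -> SimulationConfig:
        cfg = base or SimulationConfig()
        scale = SCALES[self.scale]
        cfg = replace(
            cfg,
            **PRESETS[self.name],
            generations=(
                self.generations if self.generations is not None
                else scale["generations"]
            ),
            sampling_points=(
                self.sampling_points if self.sampling_points is not None
                else scale["sampling_points"]
            ),
        )
        if self.initial_capacity is not None:
            cfg = replace(cfg, initial_lex_capacity=self.initial_capacity)
        return cfg

    @property
    def n_replicates(self) -> int:
        return (
            self.replicates if self.replicates is not None
            else SCALES[self.scale]["replicates"]
        )


def run_seed(master_seed: int, condition: str, replicate: int) -> int:
    """Per-run seed: stable hash of (condition, replicate) mixed with the
    master seed, so conditions share comparable randomness."""
    tag = zlib.crc32(f"{condition}:{replicate}".encode())
    return (master_seed * 1_000_003 + tag) % (2**31)


def run_replicates(
    cfg: SimulationConfig, condition: str, replicates: int, master_seed: int
) -> list[RunTrajectory]:
    return [
        run_simulation(cfg, seed=run_seed(master_seed, condition, rep))
        for rep in range(replicates)
    ]


def run_experiment(
    preset: ExperimentPreset,
    seed: int,
    out_dir: str | Path,
    base_config: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """Run a preset's replicates and write trajectories + summaries.

    The output directory receives ``trajectories.csv`` (long format),
    ``summary.csv`` (per-run Gen / peak UR), ``marginal_means.csv`` and a
    ``manifest.json`` with the full config, seed and code version -- enough
    to re-run bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = preset.build_config(base_config)
    trajectories = run_replicates(cfg, preset.name, preset.n_replicates, seed)
    runs = [(i, preset.name, t) for i, t in enumerate(trajectories)]
    frame = trajectories_to_frame(runs)
    frame.to_csv(out / "trajectories.csv", index=False)
    summary = run_summary(runs)
    summary.to_csv(out / "summary.csv", index=False)
    marginal_means(frame).to_csv(out / "marginal_means.csv", index=False)
    manifest = {
        "preset": preset.name,
        "scale": preset.scale,
        "replicates": preset.n_replicates,
        "master_seed": seed,
        "run_seeds": [
            run_seed(seed, preset.name, rep)
            for rep in range(preset.n_replicates)
        ],
        "config": cfg.to_dict(),
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return frame


def run_capacity_sweep(
    capacities: Sequence[int],
    seed: int,
    preset_name: str = "NoChange",
    scale: str = "desk",
    replicates: Optional[int] = None,
    generations: Optional[int] = None,
    sampling_points: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Initial-capacity sweep (threshold-capacity analogue).

    Runs the preset at each initial capacity and reports mean peak UR and
    mean Gen per capacity, one row each.
    """
    rows = []
    all_runs = []
    for cap in capacities:
        preset = ExperimentPreset(
            preset_name, scale=scale, replicates=replicates,
            generations=generations, sampling_points=sampling_points,
            initial_capacity=cap,
        )
        cfg = preset.build_config()
        condition = f"{preset_name}_cap{cap}"
        trajs = run_replicates(cfg, condition, preset.n_replicates, seed)
        runs = [(i, condition, t) for i, t in enumerate(trajs)]
        all_runs.extend(runs)
        summary = run_summary(runs)
        rows.append(
            {
                "capacity": cap,
                "mean_peak_ur": summary["peak_ur"].mean(),
                "sem_peak_ur": summary["peak_ur"].sem(),
                "mean_gen": summary["gen"].mean(),
                "sem_gen": summary["gen"].sem(),
                "n_runs": len(trajs),
            }
        )
    table = pd.DataFrame(rows).fillna(0.0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep.csv", index=False)
        trajectories_to_frame(all_runs).to_csv(
            out / "trajectories.csv", index=False
        )
    return table


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------


def worked_example_agent(space: Optional[SemanticSpace] = None) -> tuple[Agent, Meaning]:
    """The printed worked-example inventory.

    Three compositional rules (an S entity at strength 0.7, a V
    double-argument predicate at 0.6, an O entity at 0.5), S/V/O categories
    with association weights 0.7 (S member), 0.6 (V member), 0.5 (O member),
    and order rules S<<V at 0.8 and S<<O at 0.4.  Scoring the candidate set
    for the double-argument meaning returns lexical contribution 0.6,
    syntactic contribution 0.38, combined strength 0.98, and the utterance
    is the S fragment followed by V and O in either order.
    """
    space = space or SemanticSpace(4, 4, 4)
    agent = Agent(40)
    wolf, fox = 0, 1
    fight = space.double_preds[0]
    r_wolf = agent.insert_lex(
        LexicalRule("bc", constituents=frozenset({wolf}), strength=0.7)
    )
    r_fight = agent.insert_lex(
        LexicalRule("e", constituents=frozenset({fight}), strength=0.6)
    )
    r_fox = agent.insert_lex(
        LexicalRule("a", constituents=frozenset({fox}), strength=0.5)
    )
    cat_s = Category("S")
    cat_s.add_member(r_wolf, 0.7)
    cat_v = Category("V")
    cat_v.add_member(r_fight, 0.6)
    cat_o = Category("O")
    cat_o.add_member(r_fox, 0.5)
    for cat in (cat_s, cat_v, cat_o):
        agent.insert_cat(cat)
    agent.insert_syn(SyntacticRule("S", "V", strength=0.8))
    agent.insert_syn(SyntacticRule("S", "O", strength=0.4))
    return agent, Meaning(fight, wolf, fox)


def category_learning_agent(space: Optional[SemanticSpace] = None) -> Agent:
    """The printed STM contents and lexical rules of the category-learning
    example: two entity rules, two single-predicate rules, and three STM
    mappings in which both entity fragments precede the predicate
    fragments."""
    space = space or SemanticSpace(4, 4, 4)
    agent = Agent(40)
    wolf, fox = 0, 1
    run_p = space.single_preds[0]
    jump_p = space.single_preds[1]
    agent.insert_lex(LexicalRule("d", constituents=frozenset({wolf})))
    agent.insert_lex(LexicalRule("m", constituents=frozenset({run_p})))
    agent.insert_lex(LexicalRule("ac", constituents=frozenset({fox})))
    agent.insert_lex(LexicalRule("b", constituents=frozenset({jump_p})))
    from .memory import MUMapping

    agent.stm_insert(MUMapping(Meaning(run_p, wolf), "dm", agent.next_arrival()))
    agent.stm_insert(MUMapping(Meaning(run_p, fox), "acm", agent.next_arrival()))
    agent.stm_insert(MUMapping(Meaning(jump_p, wolf), "db", agent.next_arrival()))
    return agent


def converged_population(
    space: Optional[SemanticSpace] = None, n_agents: int = 10
) -> tuple[Population, SemanticSpace]:
    """A hand-built fully compositional shared language (SVO order).

    Every constituent gets a two-syllable fragment built from characters
    unique to it, all strengths and association weights are 1.0, and the
    order rules S<<V, S<<O, V<<O are shared.  The population understands the
    whole space: UR = 1.0.
    """
    space = space or SemanticSpace(4, 4, 4)
    n = space.n_constituents
    from .semantics import ALPHABET

    if 2 * n > len(ALPHABET):
        raise ValueError("not enough alphabet symbols for unique fragments")
    fragments = {c: ALPHABET[2 * c: 2 * c + 2] for c in range(n)}
    agents = []
    for _ in range(n_agents):
        agent = Agent(40)
        rules = {}
        for c, frag in fragments.items():
            rules[c] = agent.insert_lex(
                LexicalRule(frag, constituents=frozenset({c}), strength=1.0)
            )
        cat_s = Category("S")
        cat_o = Category("O")
        for e in space.entities:
            cat_s.add_member(rules[e], 1.0)
            cat_o.add_member(rules[e], 1.0)
        cat_v = Category("V")
        for p in list(space.single_preds) + list(space.double_preds):
            cat_v.add_member(rules[p], 1.0)
        for cat in (cat_s, cat_v, cat_o):
            agent.insert_cat(cat)
        agent.insert_syn(SyntacticRule("S", "V", strength=1.0))
        agent.insert_syn(SyntacticRule("S", "O", strength=1.0))
        agent.insert_syn(SyntacticRule("V", "O", strength=1.0))
        agents.append(agent)
    return Population(agents), space


def initial_population(
    seed: int = 0, cfg: Optional[SimulationConfig] = None
) -> tuple[Population, SemanticSpace]:
    """The first generation: shared holistic seed rules (UR = 0.125 on the
    64-meaning space)."""
    import random as _random

    cfg = cfg or SimulationConfig()
    space = SemanticSpace(cfg.n_entities, cfg.n_single, cfg.n_double)
    pop = init_population(cfg, space, _random.Random(seed))
    return pop, space


def make_fixture(name: str, seed: int = 0):
    """Build a named reference state: ``worked_example``,
    ``category_learning``, ``converged`` or ``initial``."""
    if name == "worked_example":
        return worked_example_agent()
    if name == "category_learning":
        return category_learning_agent()
    if name == "converged":
        return converged_population()
    if name == "initial":
        return initial_population(seed)
    raise ValueError(f"unknown fixture {name!r}")
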