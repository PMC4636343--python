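"""Run configuration: communication, memory, and evolutionary parameters.

Defaults are the study conditions of the model: a 10-agent population over a
64-meaning space (4 entities, 4 single- and 4 double-argument predicates),
20 utterance exchanges per communication, creation rate 0.25, cue
reliability 0.6, cue strength = confidence threshold = 0.75, +-0.1
competition adjustment, 0.01 forgetting applied population-wide every 10
communications, STM and syntactic/category LTM capacities fixed at 40, and
per generation 100 intra- plus 200 inter-generational communications with
mutation of the lexical-LTM capacity by +-1 at rate 0.05 when enabled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    # Semantic space
    n_entities: int = 4
    n_single: int = 4
    n_double: int = 4
    # Population
    population_size: int = 10
    # Communication (Table of learning/communication parameters)
    exchanges_per_communication: int = 20
    creation_rate: float = 0.25
    cue_reliability: float = 0.6
    cue_strength: float = 0.75
    confidence_threshold: float = 0.75
    adjust_amount: float = 0.1
    forget_amount: float = 0.01
    forget_every: int = 10  # communications between population-wide forgetting
    # Memory capacities
    stm_capacity: int = 40
    syn_capacity: int = 40
    cat_capacity: int = 40
    initial_lex_capacity: int = 30
    capacity_sd: float = 5.0
    min_capacity: int = 1
    # Generational framework
    intra_transmissions: int = 100
    inter_transmissions: int = 200
    natural_selection: bool = False
    cultural_selection: bool = False
    mutation: bool = False
    mutation_rate: float = 0.05
    mutation_step: int = 1
    # Run control
    generations: int = 200
    sampling_points: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population size must be even and >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.sampling_points < 1:
            raise ValueError("need at least one sampling point")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
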