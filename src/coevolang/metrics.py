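"""Run-level measurements: UR, the Gen statistic, peak UR, marginal means.

UR (understanding rate) is the mean communicative success over the adults of
a generation.  Gen is the fraction of the total generations elapsed before
the sampled UR first *exceeds* 0.8 (1.0 when it never does); it summarises
how quickly a widely understandable communal language emerges.  Marginal
means average UR and capacity over all sampling points and runs per
condition, with standard errors taken across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

UR_THRESHOLD = 0.8


def understanding_rate(cs: Sequence[float]) -> float:
    """Mean communicative success over all adults of a generation."""
    if not cs:
        raise ValueError("understanding rate of an empty population")
    return sum(cs) / len(cs)


@dataclass
class RunTrajectory:
    """Sampled (generation, UR, mean lexical-LTM capacity) triples."""

    generations: list[int]
    ur: list[float]
    mean_capacity: list[float]
    total_generations: int
    config: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.generations) == len(self.ur) == len(self.mean_capacity)):
            raise ValueError("trajectory columns must have equal length")
        if any(b <= a for a, b in zip(self.generations, self.generations[1:])):
            raise ValueError("generations must be strictly increasing")

    def samples(self):
        return list(zip(self.generations, self.ur, self.mean_capacity))

    def to_frame(self, run_id: int = 0, condition: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": run_id,
                "condition": condition,
                "generation": self.generations,
                "ur": self.ur,
                "mean_ltm_capacity": self.mean_capacity,
            }
        )


def gen_statistic(
    trajectory: RunTrajectory, threshold: float = UR_THRESHOLD
) -> float:
    """Fraction of generations until the sampled UR first exceeds the
    threshold; 1.0 if it never does."""
    if not trajectory.generations:
        raise ValueError("empty trajectory")
    total = trajectory.total_generations
    for g, ur in zip(trajectory.generations, trajectory.ur):
        if ur > threshold:
            return g / total if total > 0 else 0.0
    return 1.0


def peak_ur(trajectory: RunTrajectory) -> float:
    """Highest UR over all sampling points."""
    if not trajectory.ur:
        raise ValueError("empty trajectory")
    return max(trajectory.ur)


def trajectories_to_frame(
    runs: Iterable[tuple[int, str, RunTrajectory]]
) -> pd.DataFrame:
    """Long-format table from ``(run_id, condition, trajectory)`` triples."""
    frames = [t.to_frame(run_id, cond) for run_id, cond, t in runs]
    if not frames:
        return pd.DataFrame(
            columns=["run_id", "condition", "generation", "ur",
                     "mean_ltm_capacity"]
        )
    return pd.concat(frames, ignore_index=True)


def run_summary(
    runs: Iterable[tuple[int, str, RunTrajectory]],
    threshold: float = UR_THRESHOLD,
) -> pd.DataFrame:
    """Per-run summary: Gen and peak UR."""
    rows = [
        {
            "run_id": run_id,
            "condition": cond,
            "gen": gen_statistic(t, threshold),
            "peak_ur": peak_ur(t),
            "final_ur": t.ur[-1],
            "final_mean_capacity": t.mean_capacity[-1],
            "seed": t.seed,
        }
        for run_id, cond, t in runs
    ]
    return pd.DataFrame(rows)


def marginal_means(
    frame: pd.DataFrame, expected_conditions: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Condition-level marginal means of UR and capacity.

    Each run is first averaged over its sampling points; the condition mean
    and standard error are then taken across runs, matching error bars drawn
    over replicate simulations.  Missing expected conditions raise.
    """
    if frame.empty:
        raise ValueError("no runs to summarise")
    if expected_conditions is not None:
        missing = set(expected_conditions) - set(frame["condition"].unique())
        if missing:
            raise ValueError(f"missing conditions: {sorted(missing)}")
    per_run = (
        frame.groupby(["condition", "run_id"])[["ur", "mean_ltm_capacity"]]
        .mean()
        .reset_index()
    )
    out = (
        per_run.groupby("condition")
        .agg(
            mean_ur=("ur", "mean"),
            sem_ur=("ur", "sem"),
            mean_capacity=("mean_ltm_capacity", "mean"),
            sem_capacity=("mean_ltm_capacity", "sem"),
            n_runs=("run_id", "count"),
        )
        .reset_index()
    )
    return out.fillna(0.0)
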