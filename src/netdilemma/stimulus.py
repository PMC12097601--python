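"""Controlled-stimulus protocol: one focal agent, four scripted neighbors.

The focal agent starts with four cooperative neighbors.  After
``change_round`` all-C rounds the neighborhood degrades to a fixed number of
cooperators — 3 (condition A), 2 (condition B), or 1 (condition C) — and
stays there.  The protocol runs 25 rounds and is averaged over 10 independent
runs by default; the three conditions are independent experiments.

Only the focal agent's behavior is measured.  Its payoff each round is the
standard engine quantity on a degree-4 neighborhood; the scripted neighbors
have no payoffs (they are stimuli, not players).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .agents import C, D, AgentSpec, Observation, act
from .engine import AgentFailureError
from .metrics import MetricSeries, mean_with_se

__all__ = [
    "StimulusSchedule",
    "make_stimulus_schedule",
    "run_stimulus_runs",
    "run_stimulus_experiment",
    "stimulus_to_dataframe",
]

N_NEIGHBORS = 4
_COOPERATORS_AFTER = {"A": 3, "B": 2, "C": 1}


@dataclass(frozen=True)
class StimulusSchedule:
    condition: str
    rounds: int
    change_round: int
    neighbor_actions: Callable[[int], Tuple[str, str, str, str]]


def make_stimulus_schedule(
    condition: str, rounds: int = 25, change_round: int = 5
) -> StimulusSchedule:
    """Deterministic neighbor-action schedule for one condition.

    Rounds 0..change_round-1: all four neighbors cooperate.  From
    ``change_round`` on, the cooperator count is fixed at 3/2/1 for
    conditions A/B/C; defectors occupy the lowest slot indices.
    """
    if condition not in _COOPERATORS_AFTER:
        raise ValueError(f"unknown stimulus condition {condition!r}; use A, B or C")
    if not 0 < change_round < rounds:
        raise ValueError("need 0 < change_round < rounds")
    n_coop_after = _COOPERATORS_AFTER[condition]
    before = (C,) * N_NEIGHBORS
    after = (D,) * (N_NEIGHBORS - n_coop_after) + (C,) * n_coop_after

    def neighbor_actions(r: int) -> Tuple[str, ...]:
        if not 0 <= r < rounds:
            raise ValueError(f"round {r} outside schedule 0..{rounds - 1}")
        return before if r < change_round else after

    return StimulusSchedule(condition, rounds, change_round, neighbor_actions)


def _focal_payoff(
    focal_action: str,
    neighbor_actions: Tuple[str, ...],
    benefit_cost_ratio: float,
    unit_cost: float,
) -> float:
    n_coop = sum(a == C for a in neighbor_actions)
    benefit = unit_cost * benefit_cost_ratio * n_coop
    cost = unit_cost * N_NEIGHBORS if focal_action == C else 0.0
    return benefit - cost


def run_stimulus_runs(
    focal_spec: AgentSpec,
    condition: str,
    runs: int = 10,
    seed: int = 0,
    rounds: int = 25,
    change_round: int = 5,
    benefit_cost_ratio: float = 6.0,
    unit_cost: float = 10.0,
) -> Tuple[List[List[float]], int]:
    """Per-run focal cooperation indicator series.

    Schedules are deterministic and seed-independent; only the focal agent
    consumes randomness (one substream per run and round).  A focal-agent
    failure excludes that run; the failure count is returned alongside.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    schedule = make_stimulus_schedule(condition, rounds, change_round)
    series: List[List[float]] = []
    n_failed = 0
    for run in range(runs):
        own_actions: List[float] = []
        last_action: Optional[str] = None
        last_payoff: Optional[float] = None
        failed = False
        for r in range(rounds):
            if r == 0:
                obs = Observation(
                    round_index=0,
                    neighbor_slots=tuple((s, None) for s in range(N_NEIGHBORS)),
                )
            else:
                prev = schedule.neighbor_actions(r - 1)
                obs = Observation(
                    round_index=r,
                    neighbor_slots=tuple(enumerate(prev)),
                    own_last_action=last_action,
                    own_last_payoff=last_payoff,
                    frac_coop_neighbors_last=sum(a == C for a in prev)
                    / N_NEIGHBORS,
                )
            rng = np.random.default_rng([seed & 0x7FFFFFFF, run, r])
            try:
                a = act(focal_spec, obs, rng)
            except AgentFailureError:
                failed = True
                break
            own_actions.append(1.0 if a == C else 0.0)
            last_action = a
            last_payoff = _focal_payoff(
                a, schedule.neighbor_actions(r), benefit_cost_ratio, unit_cost
            )
        if failed:
            n_failed += 1
        else:
            series.append(own_actions)
    return series, n_failed


def run_stimulus_experiment(
    focal_spec: AgentSpec,
    condition: str,
    runs: int = 10,
    seed: int = 0,
    rounds: int = 25,
    change_round: int = 5,
    benefit_cost_ratio: float = 6.0,
    unit_cost: float = 10.0,
) -> MetricSeries:
    """Mean focal cooperation per round across runs, with one-SE bands."""
    series, n_failed = run_stimulus_runs(
        focal_spec,
        condition,
        runs=runs,
        seed=seed,
        rounds=rounds,
        change_round=change_round,
        benefit_cost_ratio=benefit_cost_ratio,
        unit_cost=unit_cost,
    )
    if not series:
        raise AgentFailureError(
            f"all {runs} stimulus runs failed for condition {condition}"
        )
    return mean_with_se(series)


def stimulus_to_dataframe(condition: str, series: MetricSeries) -> pd.DataFrame:
    """Output table: condition, round, mean_cooperation, se, n_runs."""
    return pd.DataFrame(
        {
            "condition": condition,
            "round": range(len(series.values)),
            "mean_cooperation": series.values,
            "se": series.se if series.se is not None else [None] * len(series.values),
            "n_runs": series.n_runs,
        }
    )
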