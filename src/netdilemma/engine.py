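"""Repeated Prisoner's Dilemma engine.

Payoff scheme: cooperation means paying a per-neighbor cost (``unit_cost``,
default 10 points) to deliver each neighbor a benefit of
``unit_cost * (b/c)`` points; defection does nothing.  A cooperator with
degree k therefore pays a total cost of 10k points per round, and mutual
cooperation on an edge nets each endpoint ``b - c`` points.  Formally

    payoff_i = sum_{j in N(i)} unit_cost * (b/c) * 1{a_j = C}
               - unit_cost * deg(i) * 1{a_i = C}

All moves within a round are simultaneous: every agent is queried with an
observation built purely from previous rounds before any current action is
revealed.

Randomness: one master seed per experiment; per-round and per-agent
substreams are derived by counter (round index, player index), so neither
agent iteration order nor the number of draws an agent consumes can perturb
any other agent's stream.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .agents import (
    C,
    D,
    Agent,
    AgentSpec,
    Observation,
    make_population,
)
from .topology import (
    InfeasibleTopologyError,
    Topology,
    TopologyMode,
    make_ring,
    resample_well_mixed,
)

__all__ = [
    "GameConfig",
    "RoundRecord",
    "ExperimentLog",
    "AgentFailureError",
    "compute_payoffs",
    "run_round",
    "run_experiment",
    "run_grid",
]

logger = logging.getLogger(__name__)

_STREAM_ACTION = 1
_STREAM_TOPOLOGY = 2
_STREAM_SLOTS = 3


class AgentFailureError(RuntimeError):
    """An agent could not produce an action; the experiment is deemed failed."""


@dataclass(frozen=True)
class GameConfig:
    """All parameters of one repeated-game experiment.

    Defaults follow the printed protocol: 10-point per-neighbor cost, degree
    and benefit-to-cost ratio drawn from the {2,4,6} x {2,4,6} grid, 8 or 25
    players, five repetitions for averages.
    """

    n_players: int
    degree: int
    benefit_cost_ratio: float
    rounds: int
    unit_cost: float = 10.0
    topology_mode: str = "ring"  # "ring" | "well_mixed"
    repetitions: int = 1
    seed: int = 0
    reveal_neighbor_payoffs: bool = False

    def __post_init__(self) -> None:
        if self.benefit_cost_ratio <= 1:
            raise ValueError("benefit_cost_ratio must exceed 1 (b > c)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.topology_mode not in ("ring", "well_mixed"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")
        if self.n_players <= self.degree:
            raise InfeasibleTopologyError(
                f"n_players={self.n_players} must exceed degree={self.degree}"
            )


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    topology: Topology
    actions: Tuple[str, ...]
    payoffs: Tuple[float, ...]


@dataclass
class ExperimentLog:
    config: GameConfig
    agent_specs: List[dict]
    records: List[RoundRecord] = field(default_factory=list)
    status: str = "completed"  # "completed" | "failed"
    repetition: int = 0

    def cooperation_series(self) -> List[float]:
        return [
            sum(a == C for a in r.actions) / len(r.actions) for r in self.records
        ]

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "agent_specs": self.agent_specs,
            "status": self.status,
            "repetition": self.repetition,
            "records": [
                {
                    "round": r.round_index,
                    "edges": sorted(map(list, r.topology.adjacency)),
                    "actions": list(r.actions),
                    "payoffs": list(r.payoffs),
                }
                for r in self.records
            ],
        }

    def to_json(self, indent: Optional[int] = None) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentLog":
        cfg = GameConfig(**data["config"])
        mode = (
            TopologyMode.RING
            if cfg.topology_mode == "ring"
            else TopologyMode.WELL_MIXED_DRAW
        )
        records = [
            RoundRecord(
                round_index=r["round"],
                topology=Topology(
                    cfg.n_players,
                    cfg.degree,
                    frozenset((min(i, j), max(i, j)) for i, j in r["edges"]),
                    mode,
                ),
                actions=tuple(r["actions"]),
                payoffs=tuple(r["payoffs"]),
            )
            for r in data["records"]
        ]
        return cls(
            config=cfg,
            agent_specs=data.get("agent_specs", []),
            records=records,
            status=data.get("status", "completed"),
            repetition=data.get("repetition", 0),
        )

    @classmethod
    def from_json(cls, text: str) -> "ExperimentLog":
        return cls.from_dict(json.loads(text))

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (round, player)."""
        rows = []
        for r in self.records:
            for p, (a, pay) in enumerate(zip(r.actions, r.payoffs)):
                rows.append(
                    {
                        "repetition": self.repetition,
                        "round": r.round_index,
                        "player": p,
                        "action": a,
                        "payoff": pay,
                        "condition_k": self.config.degree,
                        "condition_ratio": self.config.benefit_cost_ratio,
                        "topology_mode": self.config.topology_mode,
                    }
                )
        return pd.DataFrame(rows)


def compute_payoffs(
    topology: Topology,
    actions: Sequence[str],
    benefit_cost_ratio: float,
    unit_cost: float = 10.0,
) -> np.ndarray:
    """Per-player round payoffs under the cost/benefit scheme.

    Exactly conserves ``sum(payoffs) = unit_cost*(b/c - 1) * sum of
    cooperator degrees``.
    """
    if len(actions) != topology.n_players:
        raise ValueError(
            f"got {len(actions)} actions for {topology.n_players} players"
        )
    bad = set(actions) - {C, D}
    if bad:
        raise ValueError(f"invalid action(s) {bad!r}; only 'C'/'D' allowed")
    coop = np.array([a == C for a in actions], dtype=float)
    benefit = unit_cost * benefit_cost_ratio
    payoffs = np.zeros(topology.n_players)
    for i, j in topology.adjacency:
        payoffs[i] += benefit * coop[j]
        payoffs[j] += benefit * coop[i]
    payoffs -= unit_cost * topology.degree * coop
    return payoffs


def _substream(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *keys])


def _build_observation(
    player: int,
    round_index: int,
    history: Sequence[RoundRecord],
    current_topology: Topology,
    reveal_neighbor_payoffs: bool,
    slot_rng: Optional[np.random.Generator],
) -> Observation:
    """Assemble what ``player`` sees before acting this round.

    Last-round information refers to the partners the player actually
    interacted with last round (identical to the current partners on a ring).
    In well-mixed mode slot labels are a fresh random permutation each round,
    so labels carry no partner identity across rounds.
    """
    degree = current_topology.degree
    if not history:
        labels = list(range(degree))
        if slot_rng is not None:
            labels = list(slot_rng.permutation(degree))
        return Observation(
            round_index=round_index,
            neighbor_slots=tuple((int(l), None) for l in labels),
        )
    prev = history[-1]
    prev_neighbors = prev.topology.neighbors(player)
    order = list(range(len(prev_neighbors)))
    if slot_rng is not None:
        order = list(slot_rng.permutation(len(prev_neighbors)))
    slots = tuple(
        (int(slot), prev.actions[prev_neighbors[idx]])
        for slot, idx in zip(order, range(len(prev_neighbors)))
    )
    # relabel so neighbor_slots is ordered by slot label
    slots = tuple(sorted(slots, key=lambda t: t[0]))
    # align payoffs with the sorted slot order
    pay = None
    if reveal_neighbor_payoffs:
        by_slot = sorted(
            zip(order, range(len(prev_neighbors))), key=lambda t: t[0]
        )
        pay = tuple(prev.payoffs[prev_neighbors[idx]] for _, idx in by_slot)
    n_coop = sum(prev.actions[j] == C for j in prev_neighbors)
    return Observation(
        round_index=round_index,
        neighbor_slots=slots,
        own_last_action=prev.actions[player],
        own_last_payoff=prev.payoffs[player],
        frac_coop_neighbors_last=n_coop / len(prev_neighbors),
        neighbor_last_payoffs=pay,
    )


def run_round(
    topology: Topology,
    agents: Sequence[Agent],
    history: Sequence[RoundRecord],
    rng: np.random.Generator,
    *,
    benefit_cost_ratio: float,
    unit_cost: float = 10.0,
    reveal_neighbor_payoffs: bool = False,
    randomize_slots: bool = False,
) -> RoundRecord:
    """Play one simultaneous round and return its record.

    ``rng`` is split into independent per-agent substreams (slot shuffles
    first, action draws second) so that querying order is irrelevant.
    """
    n = topology.n_players
    if len(agents) != n:
        raise ValueError(f"need {n} agents, got {len(agents)}")
    round_index = len(history)
    children = rng.spawn(2 * n)
    slot_rngs, act_rngs = children[:n], children[n:]
    actions = []
    for i, agent in enumerate(agents):
        obs = _build_observation(
            i,
            round_index,
            history,
            topology,
            reveal_neighbor_payoffs,
            slot_rngs[i] if randomize_slots else None,
        )
        a = agent.act(obs, act_rngs[i])
        if a not in (C, D):
            raise AgentFailureError(
                f"agent {i} returned invalid action {a!r}"
            )
        actions.append(a)
    payoffs = compute_payoffs(topology, actions, benefit_cost_ratio, unit_cost)
    return RoundRecord(
        round_index=round_index,
        topology=topology,
        actions=tuple(actions),
        payoffs=tuple(float(p) for p in payoffs),
    )


AgentFactory = Union[
    Sequence[AgentSpec], Callable[[GameConfig], Sequence[AgentSpec]]
]


def _resolve_specs(agent_factory: AgentFactory, config: GameConfig) -> List[AgentSpec]:
    if callable(agent_factory):
        specs = list(agent_factory(config))
    else:
        specs = list(agent_factory)
    return specs


def run_experiment(
    config: GameConfig,
    agent_factory: AgentFactory,
    repetition: int = 0,
) -> ExperimentLog:
    """Run one realization of the repeated game.

    In ring mode the topology and slot labels are fixed for the whole run; in
    well-mixed mode a fresh k-regular graph is drawn and slot labels are
    re-randomized every round.  Fixed config (incl. seed) implies a
    bit-identical log.

    An agent failure (see :class:`AgentFailureError`) marks the log
    ``status="failed"`` and retains the truncated records.
    """
    specs = _resolve_specs(agent_factory, config)
    agents = make_population(specs, config)
    well_mixed = config.topology_mode == "well_mixed"
    ring = make_ring(config.n_players, config.degree)
    log = ExperimentLog(
        config=config,
        agent_specs=[s.to_dict() for s in specs],
        repetition=repetition,
    )
    for r in range(config.rounds):
        if well_mixed:
            topo_rng = _substream(config.seed, _STREAM_TOPOLOGY, repetition, r)
            topology = resample_well_mixed(config.n_players, config.degree, topo_rng)
        else:
            topology = ring
        round_rng = _substream(config.seed, _STREAM_ACTION, repetition, r)
        try:
            record = run_round(
                topology,
                agents,
                log.records,
                round_rng,
                benefit_cost_ratio=config.benefit_cost_ratio,
                unit_cost=config.unit_cost,
                reveal_neighbor_payoffs=config.reveal_neighbor_payoffs,
                randomize_slots=well_mixed,
            )
        except AgentFailureError as exc:
            logger.warning("experiment failed at round %d: %s", r, exc)
            log.status = "failed"
            return log
        log.records.append(record)
    return log


def _repetition_seed(base_seed: int, mode: str, k: int, ratio: float, rep: int) -> int:
    mode_id = 0 if mode == "ring" else 1
    ss = np.random.SeedSequence(
        [base_seed & 0x7FFFFFFF, mode_id, k, int(round(ratio * 1000)), rep]
    )
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def run_grid(
    base_config: GameConfig,
    k_values: Sequence[int],
    ratio_values: Sequence[float],
    agent_factory: AgentFactory,
    topology_modes: Sequence[str] = ("ring", "well_mixed"),
) -> Dict[Tuple[str, int, float], List[ExperimentLog]]:
    """Run the full (k, b/c) grid for each topology mode.

    One entry per (mode, k, b/c); each entry holds ``repetitions`` logs whose
    seeds are derived deterministically from the base seed.  Infeasible
    (n, k) pairs are skipped with a warning.
    """
    out: Dict[Tuple[str, int, float], List[ExperimentLog]] = {}
    for mode, k, ratio in itertools.product(
        sorted(topology_modes), sorted(k_values), sorted(ratio_values)
    ):
        if k >= base_config.n_players or k % 2 != 0:
            warnings.warn(
                f"skipping infeasible condition (n={base_config.n_players}, k={k})"
            )
            continue
        logs = []
        for rep in range(base_config.repetitions):
            cfg = GameConfig(
                n_players=base_config.n_players,
                degree=k,
                benefit_cost_ratio=ratio,
                rounds=base_config.rounds,
                unit_cost=base_config.unit_cost,
                topology_mode=mode,
                repetitions=base_config.repetitions,
                seed=_repetition_seed(base_config.seed, mode, k, ratio, rep),
                reveal_neighbor_payoffs=base_config.reveal_neighbor_payoffs,
            )
            logs.append(run_experiment(cfg, agent_factory, repetition=rep))
        out[(mode, k, ratio)] = logs
    return out


def grid_to_dataframe(
    grid: Dict[Tuple[str, int, float], List[ExperimentLog]]
) -> pd.DataFrame:
    """Concatenate all grid logs into one long-format table."""
    frames = [log.to_dataframe() for logs in grid.values() for log in logs]
    return pd.concat(frames, ignore_index=True)
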