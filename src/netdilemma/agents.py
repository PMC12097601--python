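"""Parameterized synthetic players.

These agents are the synthetic-data generator of the project: they stand in
for chat-based (LLM) and human players and are parameterized to emulate the
behavioral regimes observed in multi-agent dilemma experiments —

* sustained cooperation among cooperative neighbors and collapse once the
  neighborhood defects (the conditional cooperator),
* deterministic period-two cycling (C, D, C, D, ...), an artifact regime
  seen in some chat models but not in humans,
* indifferent coin-flip play (``random_p`` with p = 0.5),
* payoff-driven imitation of the most successful neighbor.

The conditional cooperator is a minimal 3-parameter logistic model

    P(C at round t) = logistic(alpha + beta * f_{t-1} + gamma * 1{a_{t-1} = C})

where ``f_{t-1}`` is the fraction of the agent's neighbors that cooperated
last round and ``a_{t-1}`` is the agent's own last action.  Round 0 uses an
explicit initial cooperation probability ``p0`` (default 1.0: agents start
cooperatively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "C",
    "D",
    "Observation",
    "AgentSpec",
    "Agent",
    "ContractError",
    "act",
    "make_population",
    "logistic",
]

C = "C"
D = "D"

AGENT_KINDS = (
    "always_c",
    "always_d",
    "random_p",
    "period_two",
    "conditional",
    "imitate_best",
    "llm_adapter",
)


class ContractError(ValueError):
    """An observation or spec violates an agent-kind contract."""


@dataclass(frozen=True)
class Observation:
    """What one agent sees before acting in a round.

    ``neighbor_slots`` pairs an opaque slot label with that slot's last-round
    action (``None`` in round 0).  On a ring the labels are stable across
    rounds; in the well-mixed condition they are freshly randomized every
    round so no partner identity leaks through.
    """

    round_index: int
    neighbor_slots: Tuple[Tuple[int, Optional[str]], ...]
    own_last_action: Optional[str] = None
    own_last_payoff: Optional[float] = None
    frac_coop_neighbors_last: Optional[float] = None
    neighbor_last_payoffs: Optional[Tuple[float, ...]] = None

    @property
    def degree(self) -> int:
        return len(self.neighbor_slots)


@dataclass(frozen=True)
class AgentSpec:
    """Declarative description of one synthetic agent."""

    kind: str
    params: dict = field(default_factory=dict)
    seed_offset: int = 0
    # backend is only used by kind="llm_adapter": a callable text -> text
    backend: Optional[object] = None

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ContractError(f"unknown agent kind {self.kind!r}")
        if self.kind == "random_p":
            p = self.params.get("p")
            if p is None or not (0.0 <= p <= 1.0):
                raise ContractError("random_p requires p in [0, 1]")
        if self.kind == "period_two":
            if self.params.get("start", C) not in (C, D):
                raise ContractError("period_two start must be 'C' or 'D'")
        if self.kind == "llm_adapter" and self.backend is None:
            raise ContractError("llm_adapter spec requires a backend callable")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params),
                "seed_offset": self.seed_offset}


def logistic(x: float) -> float:
    # scipy.special.expit without the import cost on the hot path
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return z / (1.0 + z)


def _conditional_prob(spec: AgentSpec, obs: Observation) -> float:
    if obs.round_index == 0:
        return float(spec.params.get("p0", 1.0))
    if obs.frac_coop_neighbors_last is None:
        raise ContractError(
            "conditional agent needs frac_coop_neighbors_last after round 0"
        )
    alpha = float(spec.params.get("alpha", 0.0))
    beta = float(spec.params.get("beta", 0.0))
    gamma = float(spec.params.get("gamma", 0.0))
    own_c = 1.0 if obs.own_last_action == C else 0.0
    return logistic(alpha + beta * obs.frac_coop_neighbors_last + gamma * own_c)


def act(spec: AgentSpec, observation: Observation, rng: np.random.Generator) -> str:
    """One action draw for an agent of the given kind.

    Deterministic kinds ignore ``rng``; stochastic kinds consume exactly one
    uniform draw, so substream bookkeeping in the engine stays simple.
    """
    kind = spec.kind
    if kind == "always_c":
        return C
    if kind == "always_d":
        return D
    if kind == "random_p":
        return C if rng.random() < spec.params["p"] else D
    if kind == "period_two":
        start = spec.params.get("start", C)
        first = start == C
        even = observation.round_index % 2 == 0
        return C if (first == even) else D
    if kind == "conditional":
        return C if rng.random() < _conditional_prob(spec, observation) else D
    if kind == "imitate_best":
        if observation.round_index == 0:
            p0 = float(spec.params.get("p0", 1.0))
            return C if rng.random() < p0 else D
        if observation.neighbor_last_payoffs is None:
            raise ContractError(
                "imitate_best requires neighbor payoffs "
                "(set reveal_neighbor_payoffs=True in the game config)"
            )
        payoffs = observation.neighbor_last_payoffs
        actions = [a for _, a in observation.neighbor_slots]
        best = max(payoffs)
        best_actions = {a for a, p in zip(actions, payoffs) if p == best}
        return C if C in best_actions else D  # ties break toward C
    if kind == "llm_adapter":
        from .adapter import llm_act

        return llm_act(spec, observation, rng)
    raise ContractError(f"unknown agent kind {kind!r}")


@dataclass
class Agent:
    """A spec bound to a player slot; the engine supplies per-round rngs."""

    spec: AgentSpec
    player: int

    def act(self, observation: Observation, rng: np.random.Generator) -> str:
        return act(self.spec, observation, rng)


def make_population(specs: Sequence[AgentSpec], config) -> list[Agent]:
    """Bind one spec per player index. Mixed populations are allowed.

    ``config`` is a GameConfig or a plain player count.
    """
    n_players = getattr(config, "n_players", config)
    if len(specs) != n_players:
        raise ContractError(
            f"need exactly {n_players} agent specs, got {len(specs)}"
        )
    return [Agent(spec=s, player=i) for i, s in enumerate(specs)]
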