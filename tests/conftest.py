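import numpy as np
import pytest

from netdilemma.agents import AgentSpec
from netdilemma.engine import GameConfig, run_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ring_log():
    """8 players on a k=2 ring, mixed cooperative/defecting population."""
    cfg = GameConfig(
        n_players=8, degree=2, benefit_cost_ratio=2, rounds=6, seed=11
    )
    specs = [AgentSpec("always_c")] * 4 + [AgentSpec("always_d")] * 4
    return run_experiment(cfg, specs)


def brute_force_payoffs(topology, actions, ratio, unit_cost=10.0):
    """Independent per-edge payoff accumulation (test oracle).

    Walks every edge twice (once per endpoint) and accumulates benefit
    received and cost paid separately; shares no code with the engine.
    """
    n = topology.n_players
    out = [0.0] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (min(i, j), max(i, j)) in topology.adjacency:
                if actions[j] == "C":
                    out[i] += unit_cost * ratio  # benefit from j
                if actions[i] == "C":
                    out[i] -= unit_cost  # cost of serving j
    return out
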