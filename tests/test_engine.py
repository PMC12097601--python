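import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netdilemma.agents import AgentSpec
from netdilemma.engine import (
    AgentFailureError,
    ExperimentLog,
    GameConfig,
    compute_payoffs,
    run_experiment,
    run_grid,
)
from netdilemma.topology import make_ring, resample_well_mixed

from conftest import brute_force_payoffs


class TestComputePayoffs:
    def test_all_defect_is_all_zero(self):
        t = make_ring(8, 4)
        assert compute_payoffs(t, ["D"] * 8, 6).tolist() == [0.0] * 8

    def test_mutual_cooperation_nets_b_minus_c_per_edge(self):
        # pair of cooperators on the triangle's shared edges: each edge with
        # a cooperating partner is worth b - c = 60 - 10 per endpoint
        t = make_ring(3, 2)
        pay = compute_payoffs(t, ["C", "C", "D"], 6)
        # players 0,1: benefit 60 from each other, cost 10*2; defector: 120
        assert pay.tolist() == [40.0, 40.0, 120.0]

    def test_hand_enumerated_4_ring(self):
        t = make_ring(4, 2)
        pay = compute_payoffs(t, ["C", "C", "D", "D"], 6)
        assert pay.tolist() == [40.0, 40.0, 60.0, 60.0]

    def test_shape_and_action_errors(self):
        t = make_ring(4, 2)
        with pytest.raises(ValueError, match="actions"):
            compute_payoffs(t, ["C"] * 3, 2)
        with pytest.raises(ValueError, match="invalid action"):
            compute_payoffs(t, ["C", "C", "X", "D"], 2)

    @given(
        n=st.integers(min_value=4, max_value=10),
        k=st.sampled_from([2, 4, 6]),
        ratio=st.sampled_from([2, 4, 6]),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_oracle_equivalence_and_conservation(self, n, k, ratio, seed):
        if k >= n:
            return
        rng = np.random.default_rng(seed)
        t = make_ring(n, k)
        actions = ["C" if x < 0.5 else "D" for x in rng.random(n)]
        pay = compute_payoffs(t, actions, ratio)
        oracle = brute_force_payoffs(t, actions, ratio)
        np.testing.assert_allclose(pay, oracle, rtol=0, atol=0)
        n_coop_degree = sum(k for i, a in enumerate(actions) if a == "C")
        assert pay.sum() == pytest.approx(10 * (ratio - 1) * n_coop_degree)

    def test_defection_dominance(self, rng):
        # switching any single cooperator to D raises own payoff by 10k
        for _ in range(100):
            n = int(rng.integers(5, 11))
            k = int(rng.choice([2, 4]))
            if k >= n:
                continue
            t = resample_well_mixed(n, k, rng) if rng.random() < 0.5 else make_ring(n, k)
            actions = ["C" if x < 0.5 else "D" for x in rng.random(n)]
            pay = compute_payoffs(t, actions, 4)
            for i in range(n):
                if actions[i] == "C":
                    flipped = list(actions)
                    flipped[i] = "D"
                    pay2 = compute_payoffs(t, flipped, 4)
                    assert pay2[i] - pay[i] == pytest.approx(10 * k)


class TestRunExperiment:
    def test_single_round_all_cooperators(self):
        cfg = GameConfig(n_players=8, degree=2, benefit_cost_ratio=2, rounds=1, seed=0)
        log = run_experiment(cfg, [AgentSpec("always_c")] * 8)
        assert len(log.records) == 1
        assert log.cooperation_series() == [1.0]
        # each payoff = 2 neighbors * 20 benefit - 20 total cost
        assert all(p == 20.0 for p in log.records[0].payoffs)

    def test_rounds_must_be_positive(self):
        with pytest.raises(ValueError, match="rounds"):
            GameConfig(n_players=8, degree=2, benefit_cost_ratio=2, rounds=0)

    def test_dilemma_requires_b_greater_than_c(self):
        with pytest.raises(ValueError, match="benefit_cost_ratio"):
            GameConfig(n_players=8, degree=2, benefit_cost_ratio=1.0, rounds=5)

    def test_fixed_seed_bit_identical_log(self):
        cfg = GameConfig(
            n_players=8, degree=4, benefit_cost_ratio=4, rounds=10,
            topology_mode="well_mixed", seed=42,
        )
        specs = [AgentSpec("random_p", {"p": 0.5})] * 8
        a = run_experiment(cfg, specs)
        b = run_experiment(cfg, specs)
        assert a.to_json() == b.to_json()

    def test_well_mixed_resamples_topology_each_round(self):
        cfg = GameConfig(
            n_players=10, degree=2, benefit_cost_ratio=2, rounds=12,
            topology_mode="well_mixed", seed=5,
        )
        log = run_experiment(cfg, [AgentSpec("always_c")] * 10)
        adjs = {r.topology.adjacency for r in log.records}
        assert len(adjs) > 1

    def test_ring_topology_fixed_across_rounds(self, small_ring_log):
        adjs = {r.topology.adjacency for r in small_ring_log.records}
        assert len(adjs) == 1

    def test_agent_failure_truncates_log(self):
        class FailingBackend:
            calls = 0

            def __call__(self, prompt):
                FailingBackend.calls += 1
                return "no comment"

        specs = [AgentSpec("always_c")] * 7 + [
            AgentSpec("llm_adapter", backend=FailingBackend())
        ]
        cfg = GameConfig(n_players=8, degree=2, benefit_cost_ratio=2, rounds=5, seed=0)
        log = run_experiment(cfg, specs)
        assert log.status == "failed"
        assert len(log.records) == 0

    def test_json_round_trip(self, small_ring_log):
        restored = ExperimentLog.from_json(small_ring_log.to_json())
        assert restored.to_json() == small_ring_log.to_json()
        assert restored.records[0].topology.adjacency == \
            small_ring_log.records[0].topology.adjacency

    def test_long_dataframe_shape(self, small_ring_log):
        df = small_ring_log.to_dataframe()
        assert len(df) == 6 * 8
        assert set(df.columns) == {
            "repetition", "round", "player", "action", "payoff",
            "condition_k", "condition_ratio", "topology_mode",
        }


class TestRunGrid:
    def test_grid_shape_and_determinism(self):
        base = GameConfig(
            n_players=8, degree=2, benefit_cost_ratio=2, rounds=3,
            repetitions=2, seed=9,
        )
        specs = [AgentSpec("random_p", {"p": 0.5})] * 8
        grid = run_grid(base, [2, 4], [2, 6], specs)
        assert set(grid) == {
            (m, k, r) for m in ("ring", "well_mixed") for k in (2, 4) for r in (2, 6)
        }
        assert all(len(v) == 2 for v in grid.values())
        grid2 = run_grid(base, [2, 4], [2, 6], specs)
        for key in grid:
            for a, b in zip(grid[key], grid2[key]):
                assert a.to_json() == b.to_json()

    def test_infeasible_pair_skipped_with_warning(self):
        base = GameConfig(
            n_players=4, degree=2, benefit_cost_ratio=2, rounds=2, seed=0
        )
        with pytest.warns(UserWarning, match="infeasible"):
            grid = run_grid(base, [2, 6], [2], [AgentSpec("always_c")] * 4)
        assert set(k for _, k, _ in grid) == {2}

    def test_repetition_seeds_differ(self):
        base = GameConfig(
            n_players=8, degree=2, benefit_cost_ratio=2, rounds=2,
            repetitions=3, seed=1,
        )
        grid = run_grid(base, [2], [2], [AgentSpec("random_p", {"p": 0.5})] * 8)
        seeds = [log.config.seed for log in grid[("ring", 2, 2)]]
        assert len(set(seeds)) == 3
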