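import numpy as np
import pytest

from netdilemma.agents import AgentSpec, logistic
from netdilemma.engine import GameConfig, run_experiment
from netdilemma.inference import (
    detect_period_two,
    fit_conditional,
    fit_conditional_arrays,
)


def simulate_conditional(alpha, beta, gamma, n_rounds, seed, p0=0.5):
    """Scripted-neighborhood simulation of one conditional cooperator.

    Neighbor cooperation fractions cycle deterministically through
    {0, 0.25, 0.5, 0.75, 1}; the agent's own action evolves endogenously.
    Returns (frac_last, own_last_c, response_c) arrays for rounds 1..n.
    """
    rng = np.random.default_rng(seed)
    fracs = np.tile([0.0, 0.25, 0.5, 0.75, 1.0], n_rounds // 5 + 1)[: n_rounds + 1]
    own = 1.0 if rng.random() < p0 else 0.0
    X_frac, X_own, y = [], [], []
    for t in range(1, n_rounds + 1):
        p = logistic(alpha + beta * fracs[t - 1] + gamma * own)
        a = 1.0 if rng.random() < p else 0.0
        X_frac.append(fracs[t - 1])
        X_own.append(own)
        y.append(a)
        own = a
    return np.array(X_frac), np.array(X_own), np.array(y)


def grid_search_loglik(X_frac, X_own, y, lo=-4.0, hi=4.0, step=0.1):
    """Independent brute-force likelihood maximization over a lattice.

    Collapses the data to unique (frac, own) cells with counts so the full
    (alpha, beta, gamma) grid can be scanned vectorized.
    """
    cells = {}
    for f, o, yy in zip(X_frac, X_own, y):
        key = (f, o)
        n, s = cells.get(key, (0, 0.0))
        cells[key] = (n + 1, s + yy)
    keys = np.array(list(cells.keys()))  # (m, 2)
    counts = np.array([cells[tuple(k)][0] for k in keys])
    sums = np.array([cells[tuple(k)][1] for k in keys])
    axis = np.arange(lo, hi + step / 2, step)
    A, B, G = np.meshgrid(axis, axis, axis, indexing="ij")
    thetas = np.column_stack([A.ravel(), B.ravel(), G.ravel()])
    Xu = np.column_stack([np.ones(len(keys)), keys[:, 0], keys[:, 1]])
    z = thetas @ Xu.T  # (n_grid, m)
    ll = z @ sums - np.logaddexp(0.0, z) @ counts
    best = np.argmax(ll)
    return thetas[best], float(ll[best])


class TestFitConditional:
    def test_null_agent_recovers_zeros(self):
        cfg = GameConfig(
            n_players=8, degree=2, benefit_cost_ratio=2, rounds=1000, seed=17
        )
        specs = [AgentSpec("random_p", {"p": 0.5})] * 8
        log = run_experiment(cfg, specs)
        fit = fit_conditional(log, 0)
        se = fit.standard_errors
        assert not fit.boundary
        for est, s in zip(fit.params, se):
            assert abs(est) < 3 * s

    def test_parameter_recovery_within_wald_intervals(self):
        true = (-1.0, 3.0, 0.5)
        hits = 0
        for rep in range(40):
            Xf, Xo, y = simulate_conditional(*true, n_rounds=2000, seed=1000 + rep)
            fit = fit_conditional_arrays(Xf, Xo, y)
            ok = all(
                fit.wald_interval(i)[0] <= true[i] <= fit.wald_interval(i)[1]
                for i in range(3)
            )
            hits += ok
        # joint 95% coverage of 3 intervals ~ 0.86; demand a clear majority
        assert hits >= 30

    def test_boundary_flag_on_constant_responses(self):
        cfg = GameConfig(n_players=8, degree=2, benefit_cost_ratio=2, rounds=30, seed=3)
        log = run_experiment(cfg, [AgentSpec("always_c")] * 8)
        fit = fit_conditional(log, 0)
        assert fit.boundary
        assert np.all(np.isfinite(fit.params))  # penalized fallback is finite

    def test_loglik_at_mle_beats_truth(self):
        Xf, Xo, y = simulate_conditional(-1.0, 3.0, 0.5, n_rounds=500, seed=4)
        fit = fit_conditional_arrays(Xf, Xo, y)
        X = np.column_stack([np.ones_like(Xf), Xf, Xo])
        z = X @ np.array([-1.0, 3.0, 0.5])
        ll_true = y @ z - np.logaddexp(0.0, z).sum()
        assert fit.log_likelihood >= ll_true - 1e-6

    def test_agrees_with_brute_force_grid_search(self):
        Xf, Xo, y = simulate_conditional(-1.0, 2.0, 0.5, n_rounds=2000, seed=8)
        fit = fit_conditional_arrays(Xf, Xo, y)
        theta_grid, ll_grid = grid_search_loglik(Xf, Xo, y)
        assert np.max(np.abs(fit.params - theta_grid)) <= 0.1 + 1e-12
        assert fit.log_likelihood >= ll_grid - 1e-9

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        Xf, Xo, y = simulate_conditional(-0.5, 1.5, 0.8, n_rounds=1500, seed=12)
        fit = fit_conditional_arrays(Xf, Xo, y)
        X = sm.add_constant(np.column_stack([Xf, Xo]))
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-5)
        np.testing.assert_allclose(
            fit.standard_errors, ref.bse, rtol=1e-4
        )

    def test_covariance_symmetric_psd_and_loglik_nonpositive(self):
        Xf, Xo, y = simulate_conditional(-1.0, 3.0, 0.5, n_rounds=300, seed=5)
        fit = fit_conditional_arrays(Xf, Xo, y)
        assert fit.log_likelihood <= 0
        np.testing.assert_allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.linalg.eigvalsh(fit.covariance) >= -1e-10)

    def test_needs_two_rounds(self):
        cfg = GameConfig(n_players=4, degree=2, benefit_cost_ratio=2, rounds=1, seed=0)
        log = run_experiment(cfg, [AgentSpec("always_c")] * 4)
        with pytest.raises(ValueError):
            fit_conditional(log, 0)


class TestDetectPeriodTwo:
    def test_perfect_alternation(self):
        out = detect_period_two(["C", "D", "C", "D", "C", "D"])
        assert out["is_cyclic"] is True
        assert out["score"] == pytest.approx(-1.0)

    def test_constant_series_convention(self):
        out = detect_period_two(["C", "C", "C", "C"])
        assert out["is_cyclic"] is False
        assert out["score"] == 0.0

    def test_coin_flip_series_scores_near_zero(self):
        rng = np.random.default_rng(2024)
        # lag-1 autocorrelation of iid noise at n=1000 has sd ~ 1/sqrt(n)
        scores = []
        for _ in range(50):
            x = (rng.random(1000) < 0.5).astype(int)
            scores.append(detect_period_two(x)["score"])
        assert np.mean(np.abs(np.array(scores)) < 0.1) >= 0.98

    def test_noisy_cycling_scores_negative_but_not_cyclic(self):
        rng = np.random.default_rng(7)
        x = np.array([t % 2 for t in range(200)])
        flip = rng.choice(200, size=10, replace=False)
        x[flip] = 1 - x[flip]
        out = detect_period_two(x)
        assert out["is_cyclic"] is False
        assert out["score"] < -0.5

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_period_two(["C", "D", "C"])
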