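"""Policy network, PPO machinery, batched environment, deployment."""

import numpy as np
import pytest

from adadose.mcpmod import GroupSummary, analyze_trial, mct_test
from adadose.rl_policy import (
    MLP,
    BatchTrialEnv,
    PolicyNetwork,
    PPOConfig,
    TrainingConfig,
    deploy_policy,
    load_policy,
    policy_forward,
    save_policy,
    train_policy,
)
from adadose.trial_env import TrialConfig


class TestPolicyNetwork:
    def test_probabilities_valid(self, rng):
        pol = PolicyNetwork(14, 5, hidden=16, rng=rng)
        p = pol.probs(rng.normal(0, 3, (40, 14)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p > 0)

    def test_zeroed_head_is_uniform(self, rng):
        pol = PolicyNetwork(14, 5, hidden=16, rng=rng)
        pol.net.params[4][:] = 0.0
        pol.net.params[5][:] = 0.0
        p = policy_forward(pol, rng.normal(0, 1, 14))
        np.testing.assert_allclose(p, 0.2, atol=1e-12)

    def test_logit_shift_invariance(self, rng):
        pol = PolicyNetwork(14, 5, hidden=16, rng=rng)
        s = rng.normal(0, 1, 14)
        p1 = policy_forward(pol, s)
        pol.net.params[5][:] += 7.5   # constant added to every logit
        np.testing.assert_allclose(policy_forward(pol, s), p1, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        pol = PolicyNetwork(14, 5, hidden=16, rng=rng)
        with pytest.raises(ValueError):
            pol.probs(np.zeros((3, 9)))


class TestMlpGradients:
    def test_backward_matches_finite_differences(self, rng):
        net = MLP(4, 6, 3, rng, out_scale=1.0)
        X = rng.normal(0, 1, (7, 4))
        T = rng.normal(0, 1, (7, 3))

        def loss():
            return 0.5 * np.sum((net.forward(X) - T) ** 2)

        out, cache = net.forward(X, cache=True)
        grads = net.backward(cache, out - T)
        eps = 1e-6
        for pi in range(len(net.params)):
            flat = net.params[pi].ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[pi].ravel()[idx] == pytest.approx(num, abs=1e-4)


class TestDeployment:
    def test_point_mass(self, rng):
        pol = PolicyNetwork(14, 5, hidden=16, rng=rng)
        pol.net.params[5][:] = [50.0, 0, 0, 0, 0]
        counts = deploy_policy(pol, np.zeros(14), 10, rng)
        np.testing.assert_array_equal(counts, [10, 0, 0, 0, 0])

    def test_sampling_law_of_large_numbers(self, rng):
        pol = PolicyNetwork(14, 5, hidden=16, rng=rng)
        pol.net.params[4][:] = 0.0
        pol.net.params[5][:] = 0.0
        total = sum(deploy_policy(pol, np.zeros(14), 10, rng)
                    for _ in range(3000))
        np.testing.assert_allclose(total / 3000, 2.0, atol=0.12)

    def test_rounding_mode(self, rng):
        from adadose.optimal_design import efficient_round

        class _Fixed:
            state_dim, n_actions = 14, 5
            def probs(self, s):
                return np.array([[0.305, 0.195, 0.12, 0.09, 0.29]])
        counts = deploy_policy(_Fixed(), np.zeros(14), 10, rng, mode="round")
        np.testing.assert_array_equal(
            counts, efficient_round(np.array([0.305, 0.195, 0.12, 0.09, 0.29]), 10))
        assert counts.sum() == 10

    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = TrialConfig()
        tp = train_policy(metric="MAE", trial_config=cfg,
                          training=TrainingConfig(metric="MAE", episodes=1000,
                                                  episodes_per_update=1000),
                          seed=3)
        path = tmp_path / "pol.npz"
        save_policy(tp, path)
        loaded = load_policy(path)
        s = rng.normal(0, 1, (6, 14))
        np.testing.assert_allclose(loaded.policy.probs(s), tp.policy.probs(s),
                                   atol=1e-12)
        assert loaded.training.metric == "MAE"


class TestBatchEnv:
    def test_episode_bookkeeping(self, config, rng):
        env = BatchTrialEnv(config)
        s = env.reset(8, rng)
        assert s.shape == (8, 14) and env.horizon == 10
        for _ in range(env.horizon):
            s = env.step(rng.integers(0, 5, 8))
        np.testing.assert_array_equal(env._n.sum(axis=1), 150.0)
        r = env.terminal_rewards("MAE")
        assert r.shape == (8,) and np.all(r <= 1.0)

    def test_batch_analysis_matches_per_trial_path(self, config, candidates, rng):
        """The vectorized reward kernel agrees with the reference analysis
        (grid-profile mode) episode by episode."""
        env = BatchTrialEnv(config)
        env.reset(12, rng)
        for _ in range(env.horizon):
            env.step(rng.integers(0, 5, 12))
        ybar = env._sum / env._n
        ss = np.maximum(env._sumsq - env._n * ybar**2, 0.0)
        sd = np.sqrt(ss / (env._n - 1.0))
        from adadose._batch import batch_analyze
        res = batch_analyze(env._n, ybar, ss.sum(axis=1), candidates,
                            config.grid, config.delta,
                            sig_cache=env._sig_cache)
        fam_names = candidates.families
        for e in range(12):
            summ = GroupSummary(n=env._n[e].astype(int), mean=ybar[e], sd=sd[e])
            ref = analyze_trial(summ, candidates, alpha=config.alpha,
                                delta=config.delta, grid=config.grid,
                                polish=False)
            assert fam_names[res["selected"][e]] == ref.selected_family
            if ref.d_targ_hat is None:
                assert not np.isfinite(res["td_hat"][e])
            else:
                assert res["td_hat"][e] == pytest.approx(ref.d_targ_hat, abs=1e-5)
            test = mct_test(summ, candidates, alpha=config.alpha)
            assert bool(res["significant"][e]) == test.significant

    def test_reward_nan_guard(self, config, rng):
        env = BatchTrialEnv(config)
        env.reset(4, rng)
        with pytest.raises(RuntimeError):
            env.terminal_rewards("MAE")   # episodes not finished


class TestTraining:
    def test_history_and_determinism_smoke(self, config):
        tr = TrainingConfig(metric="MAE", episodes=2000, episodes_per_update=1000,
                            ppo=PPOConfig(epochs=2, minibatch=2000))
        t1 = train_policy(metric="MAE", trial_config=config, training=tr, seed=5)
        t2 = train_policy(metric="MAE", trial_config=config, training=tr, seed=5)
        assert len(t1.history) == 2
        for p1, p2 in zip(t1.policy.net.params, t2.policy.net.params):
            np.testing.assert_array_equal(p1, p2)

    def test_invalid_training_config(self):
        with pytest.raises(ValueError):
            TrainingConfig(episodes=1500, episodes_per_update=1000)


def test_default_training_scenarios_carry_target_intervals(config):
    """The TD reward needs each training scenario's target-dose interval;
    the default candidate-shape scenarios must be built with them."""
    env = BatchTrialEnv(config)
    for s in env.scenarios:
        assert s.interval is not None and s.d_targ is not None
    rng = np.random.default_rng(0)
    env.reset(100, rng)
    for _ in range(env.horizon):
        env.step(rng.integers(0, 5, 100))
    assert env.terminal_rewards("TD").mean() > 0.05
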