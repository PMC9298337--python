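"""Trial MDP: initialization, blocks, state encoding, rewards, rules."""

import numpy as np
import pytest

from adadose.dose_response import calibrate_curve
from adadose.mcpmod import AnalysisResult
from adadose.trial_env import (
    EqualAllocation,
    FixedDesign,
    RLAllocation,
    TrialConfig,
    TrialState,
    apply_block,
    encode_state,
    initialize_trial,
    run_trial,
    terminal_reward,
)


class TestConfig:
    def test_defaults(self, config):
        assert config.n_blocks == 10 and config.state_dim == 14

    def test_invalid_divisibility(self):
        with pytest.raises(ValueError):
            TrialConfig(n_initial=48)
        with pytest.raises(ValueError):
            TrialConfig(n_block=7)
        with pytest.raises(ValueError):
            TrialConfig(metric="AUC")


class TestStateMachine:
    def test_initialization(self, config, scenarios, rng):
        st = initialize_trial(config, scenarios[0].curve, rng)
        np.testing.assert_array_equal(st.n, np.full(5, 10))
        s = encode_state(st, config)
        np.testing.assert_allclose(s[-5:], np.full(5, 10 / 150))

    def test_zero_noise_flat(self, scenarios, rng):
        cfg = TrialConfig(sigma2=0.0)
        st = initialize_trial(cfg, scenarios[15].curve, rng)
        np.testing.assert_allclose(st.mean, 0.0, atol=1e-15)
        np.testing.assert_allclose(st.sd, 0.0, atol=1e-15)
        np.testing.assert_allclose(encode_state(st, cfg)[:4], 0.0)

    def test_apply_block_counts_and_overallocation(self, config, scenarios, rng):
        st = initialize_trial(config, scenarios[0].curve, rng)
        apply_block(st, [10, 0, 0, 0, 0], scenarios[0].curve, config, rng)
        assert st.n[0] == 20
        for _ in range(9):
            apply_block(st, [0, 0, 10, 0, 0], scenarios[0].curve, config, rng)
        assert st.n_allocated == config.n_total
        with pytest.raises(ValueError):
            apply_block(st, [0, 0, 10, 0, 0], scenarios[0].curve, config, rng)
        with pytest.raises(ValueError):
            apply_block(st, [3, 0, 0, 0, 0], scenarios[0].curve, config, rng)

    def test_streaming_matches_batch_recomputation(self, config, scenarios, rng):
        """Running means/SDs equal ones recomputed from raw responses."""
        st = initialize_trial(config, scenarios[3].curve, rng)
        for _ in range(4):
            apply_block(st, [2, 3, 1, 0, 4], scenarios[3].curve, config, rng)
        for k in range(5):
            r = np.array(st.responses[k])
            assert st.mean[k] == pytest.approx(r.mean(), abs=1e-12)
            assert st.sd[k] == pytest.approx(r.std(ddof=1), abs=1e-12)
        summ = st.summary()
        np.testing.assert_array_equal(summ.n, st.n)

    def test_encode_ordering(self, config):
        st = TrialState(5)
        for k in range(5):
            st.add(k, np.array([k + 0.0, k + 2.0]))   # mean k+1, sd sqrt(2)
        s = encode_state(st, config)
        np.testing.assert_allclose(s[:4], [1, 2, 3, 4])
        np.testing.assert_allclose(s[4:9], np.sqrt(2))
        np.testing.assert_allclose(s[9:], 2 / 150)

    def test_encode_needs_two_per_arm(self, config):
        st = TrialState(5)
        st.add(0, np.array([1.0]))
        with pytest.raises(ValueError):
            encode_state(st, config)


class TestRewards:
    def _analysis(self, significant=True, family="emax", d_hat=2.0, curve=None):
        curve = curve or calibrate_curve("emax", (0.79,), 1.65)
        return AnalysisResult(significant=significant, min_pvalue=0.001,
                              selected_family=family, fitted_curve=curve,
                              d_targ_hat=d_hat)

    def test_mae_reward_transform(self, scenarios, config):
        a = self._analysis(curve=scenarios[3].curve)
        assert terminal_reward("MAE", a, scenarios[3], config) == pytest.approx(1.0)
        flat = calibrate_curve("flat", (), 0.0)
        a2 = self._analysis(curve=flat)
        mae = a2.mae_against(scenarios[3].curve)
        assert terminal_reward("MAE", a2, scenarios[3], config) == pytest.approx(1 - 2 * mae)

    def test_td_reward_uses_interval(self, scenarios, config):
        a = self._analysis(d_hat=2.0)
        assert terminal_reward("TD", a, scenarios[3], config) == 1.0   # (1.44, 2.95)
        assert terminal_reward("TD", self._analysis(d_hat=3.5), scenarios[3], config) == 0.0
        assert terminal_reward("TD", self._analysis(d_hat=None), scenarios[3], config) == 0.0

    def test_flat_truth_gives_no_power_reward(self, scenarios, config):
        a = self._analysis(significant=True)
        assert terminal_reward("power", a, scenarios[15], config) == 0.0
        assert terminal_reward("power", a, scenarios[0], config) == 1.0

    def test_ms_reward(self, scenarios, config):
        a = self._analysis(family="emax")
        assert terminal_reward("MS", a, scenarios[3], config) == 1.0
        assert terminal_reward("MS", a, scenarios[0], config) == 0.0


class TestRunTrial:
    def test_equal_counts(self, config, scenarios):
        rec = run_trial(EqualAllocation(), scenarios[0], config, seed=7)
        np.testing.assert_array_equal(rec.counts, np.full(5, 30))
        assert set(rec.metrics) == {"power", "MS", "TD", "MAE"}
        assert rec.metrics["MAE"] >= 0

    def test_fixed_design_counts(self, config, scenarios):
        rule = FixedDesign([44, 30, 18, 14, 44], name="d-optimal-1")
        rec = run_trial(rule, scenarios[0], config, seed=7)
        np.testing.assert_array_equal(rec.counts, [44, 30, 18, 14, 44])

    def test_determinism(self, config, scenarios):
        r1 = run_trial(EqualAllocation(), scenarios[3], config, seed=99)
        r2 = run_trial(EqualAllocation(), scenarios[3], config, seed=99)
        assert r1.metrics == r2.metrics
        assert r1.analysis.min_pvalue == r2.analysis.min_pvalue

    def test_conservation_with_random_policy(self, config, scenarios):
        from adadose.rl_policy import PolicyNetwork
        pol = PolicyNetwork(14, 5, hidden=8, rng=np.random.default_rng(0))
        rec = run_trial(RLAllocation(pol), scenarios[0], config, seed=5)
        assert rec.counts.sum() == config.n_total
        assert np.all(rec.counts >= 10)    # burn-in floor

    def test_rmae_at_most_one(self, config, scenarios):
        for seed in range(5):
            rec = run_trial(EqualAllocation(), scenarios[0], config, seed=seed)
            assert 1 - 2 * rec.metrics["MAE"] <= 1.0


class TestAdaptiveOptimalRule:
    def test_blockwise_d_optimal_pulls_toward_fixed_design(self, config, scenarios):
        """Averaged over many trials, the blockwise D-optimal allocation moves
        from equal toward the fixed D-optimal ratios (more subjects on the
        extreme arms, fewer mid-range)."""
        from adadose.trial_env import AdaptiveOptimalAllocation

        rule = AdaptiveOptimalAllocation("D", restarts=1)
        counts = np.mean([
            run_trial(rule, scenarios[0], config, seed=1000 + i).counts
            for i in range(200)
        ], axis=0)
        assert counts.sum() == pytest.approx(config.n_total)
        target = np.array([44, 30, 18, 14, 44], dtype=float)
        equal = np.full(5, 30.0)
        assert np.abs(counts - target).sum() < np.abs(equal - target).sum()
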