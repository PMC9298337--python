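"""PPO-trained allocation policies, implemented in NumPy.

The allocation rule pi(k|s) is a two-hidden-layer ReLU network (256 units
each) with a K-way softmax head over the doses; a critic of the same
architecture supplies the baseline.  Training follows proximal policy
optimization with the clipped surrogate objective: batches of whole
simulated trials (episodes of exactly B block decisions, terminal-only
reward), one parameter update per batch of ``episodes_per_update`` trials.

During learning every block is assigned wholesale to a single dose (a
discrete action), which speeds up and stabilizes the credit assignment; at
deployment the trained probabilities are either sampled per subject or
rounded into block counts.

No deep-learning framework is assumed: forward/backward passes, Adam and
the PPO update are explicit, which keeps the dependency footprint to NumPy
and makes the arithmetic reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._batch import SignificanceCache, batch_analyze
from .dose_response import Scenario, target_dose, target_dose_interval
from .mcpmod import CandidateSet, default_candidates
from .optimal_design import efficient_round
from .trial_env import TrialConfig

__all__ = [
    "MLP",
    "PolicyNetwork",
    "PPOConfig",
    "TrainingConfig",
    "BatchTrialEnv",
    "TrainedPolicy",
    "train_policy",
    "policy_forward",
    "deploy_policy",
    "save_policy",
    "load_policy",
]


class MLP:
    """Fully connected in -> hidden -> hidden -> out with ReLU activations."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator, out_scale: float = 0.01):
        def he(fan_in, fan_out, scale):
            return rng.normal(0.0, scale / np.sqrt(fan_in), (fan_in, fan_out))

        self.params = [
            he(in_dim, hidden, np.sqrt(2.0)), np.zeros(hidden),
            he(hidden, hidden, np.sqrt(2.0)), np.zeros(hidden),
            he(hidden, out_dim, out_scale), np.zeros(out_dim),
        ]

    def forward(self, X: np.ndarray, cache: bool = False):
        W1, b1, W2, b2, W3, b3 = self.params
        z1 = X @ W1 + b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ W2 + b2
        a2 = np.maximum(z2, 0.0)
        out = a2 @ W3 + b3
        if cache:
            return out, (X, z1, a1, z2, a2)
        return out

    def backward(self, cache, dout: np.ndarray):
        X, z1, a1, z2, a2 = cache
        W1, b1, W2, b2, W3, b3 = self.params
        dW3 = a2.T @ dout
        db3 = dout.sum(axis=0)
        da2 = dout @ W3.T
        dz2 = da2 * (z2 > 0)
        dW2 = a1.T @ dz2
        db2 = dz2.sum(axis=0)
        da1 = dz2 @ W2.T
        dz1 = da1 * (z1 > 0)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dW2, db2, dW3, db3]


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class PolicyNetwork:
    """Softmax policy over the K doses given the 3K-1 dimensional state."""

    def __init__(self, state_dim: int, n_actions: int, hidden: int = 256,
                 rng: Optional[np.random.Generator] = None):
        self.state_dim = state_dim
        self.n_actions = n_actions
        self.hidden = hidden
        self.net = MLP(state_dim, hidden, n_actions,
                       rng or np.random.default_rng(0))

    def logits(self, states: np.ndarray, cache: bool = False):
        states = np.atleast_2d(states)
        if states.shape[1] != self.state_dim:
            raise ValueError(
                f"state dimension {states.shape[1]} != {self.state_dim}")
        return self.net.forward(states, cache=cache)

    def probs(self, states: np.ndarray) -> np.ndarray:
        u = self.logits(states)
        u = u - u.max(axis=1, keepdims=True)
        e = np.exp(u)
        return e / e.sum(axis=1, keepdims=True)

    def entropy(self, states: np.ndarray) -> np.ndarray:
        p = self.probs(states)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(p > 0, np.log(p), 0.0)
        return -(p * lp).sum(axis=1)


def policy_forward(policy: PolicyNetwork, state: np.ndarray) -> np.ndarray:
    """Action probabilities pi(.|s) for a single state vector."""
    return policy.probs(np.atleast_2d(state))[0]


@dataclass(frozen=True)
class PPOConfig:
    """Clipped-surrogate PPO hyperparameters (all logged with the run)."""

    learning_rate: float = 3e-4
    clip: float = 0.2
    epochs: int = 10
    minibatch: int = 1000
    vf_coef: float = 0.5
    ent_coef: float = 0.0
    discount: float = 1.0      # terminal reward, fixed short horizon


@dataclass(frozen=True)
class TrainingConfig:
    metric: str = "MAE"
    episodes: int = 1_000_000
    episodes_per_update: int = 1000
    hidden: int = 256
    ppo: PPOConfig = field(default_factory=PPOConfig)

    def __post_init__(self) -> None:
        if self.episodes % self.episodes_per_update:
            raise ValueError("episodes must be divisible by episodes_per_update")


class BatchTrialEnv:
    """Vectorized block-sequential trial environment for training.

    Each reset draws a true curve per episode uniformly from the training
    scenarios (by default the three MCP-Mod candidate shapes); each step
    assigns the whole next block of subjects to the chosen dose and returns
    the updated states.  Rewards are terminal-only and computed in bulk by
    the vectorized analysis kernels.
    """

    def __init__(self, config: TrialConfig,
                 scenarios: Optional[Sequence[Scenario]] = None,
                 candidates: Optional[CandidateSet] = None):
        self.config = config
        self.candidates = candidates or default_candidates(config.grid)
        if scenarios is None:
            scenarios = [
                Scenario(id=i + 1, curve=m.curve, max_effect=1.65,
                         d_targ=target_dose(m.curve, config.delta, config.grid),
                         interval=target_dose_interval(
                             m.curve, config.delta, config.eta, config.grid))
                for i, m in enumerate(self.candidates.models)
            ]
        self.scenarios = list(scenarios)
        d = config.grid.array()
        self._mu_table = np.stack([np.asarray(s.curve(d), dtype=float)
                                   for s in self.scenarios])
        self._eff_table = self._mu_table[:, 1:] - self._mu_table[:, :1]
        self._true_family = [s.curve.family for s in self.scenarios]
        self._fam_index = {m.family: i
                           for i, m in enumerate(self.candidates.models)}
        self._intervals = [s.interval for s in self.scenarios]
        self._sig_cache = SignificanceCache(self.candidates, config.grid,
                                            config.alpha)
        self._rng: Optional[np.random.Generator] = None

    @property
    def horizon(self) -> int:
        return self.config.n_blocks

    def reset(self, n_episodes: int, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        self._rng = rng
        self._scen_idx = rng.integers(0, len(self.scenarios), n_episodes)
        mu = self._mu_table[self._scen_idx]                  # (E, K)
        per_arm = cfg.n_initial // cfg.K
        draws = rng.normal(mu[:, :, None], np.sqrt(cfg.sigma2),
                           (n_episodes, cfg.K, per_arm))
        self._n = np.full((n_episodes, cfg.K), per_arm, dtype=float)
        self._sum = draws.sum(axis=2)
        self._sumsq = (draws**2).sum(axis=2)
        self._mu = mu
        self._steps = 0
        return self._encode()

    def step(self, actions: np.ndarray) -> np.ndarray:
        cfg = self.config
        rng = self._rng
        E = len(actions)
        rows = np.arange(E)
        mu_a = self._mu[rows, actions]
        draws = rng.normal(mu_a[:, None], np.sqrt(cfg.sigma2), (E, cfg.n_block))
        self._n[rows, actions] += cfg.n_block
        self._sum[rows, actions] += draws.sum(axis=1)
        self._sumsq[rows, actions] += (draws**2).sum(axis=1)
        self._steps += 1
        return self._encode()

    def _encode(self) -> np.ndarray:
        ybar = self._sum / self._n
        ss = np.maximum(self._sumsq - self._n * ybar**2, 0.0)
        sd = np.sqrt(ss / (self._n - 1.0))
        return np.concatenate([ybar[:, 1:] - ybar[:, :1], sd,
                               self._n / self.config.n_total], axis=1)

    def terminal_rewards(self, metric: str) -> np.ndarray:
        cfg = self.config
        if self._steps != self.horizon:
            raise RuntimeError("episode batch not yet complete")
        ybar = self._sum / self._n
        rss_within = np.maximum(self._sumsq - self._n * ybar**2, 0.0).sum(axis=1)
        need_sig = metric == "power"
        res = batch_analyze(self._n, ybar, rss_within, self.candidates,
                            cfg.grid, cfg.delta,
                            sig_cache=self._sig_cache if need_sig else None)
        E = len(self._scen_idx)
        if metric == "power":
            nonflat = np.array([self._true_family[i] != "flat"
                                for i in self._scen_idx])
            return (res["significant"] & nonflat).astype(float)
        if metric == "MS":
            true_idx = np.array([self._fam_index.get(self._true_family[i], -1)
                                 for i in self._scen_idx])
            return (res["selected"] == true_idx).astype(float)
        if metric == "TD":
            td = res["td_hat"]
            r = np.zeros(E)
            for e, i in enumerate(self._scen_idx):
                iv = self._intervals[i]
                if iv is not None and np.isfinite(td[e]):
                    r[e] = float(iv[0] <= td[e] <= iv[1])
            return r
        if metric == "MAE":
            true_eff = self._eff_table[self._scen_idx]
            mae = np.abs(res["effects"] - true_eff).mean(axis=1)
            return 1.0 - 2.0 * mae
        raise ValueError(f"unknown metric {metric!r}")


@dataclass
class TrainedPolicy:
    policy: PolicyNetwork
    history: pd.DataFrame
    training: TrainingConfig
    seed: int


def _sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random((probs.shape[0], 1))
    return (u > np.cumsum(probs, axis=1)).sum(axis=1)


def _softmax_rows(u: np.ndarray) -> np.ndarray:
    u = u - u.max(axis=1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=1, keepdims=True)


def train_policy(metric: str = "MAE",
                 trial_config: Optional[TrialConfig] = None,
                 training: Optional[TrainingConfig] = None,
                 env: Optional[BatchTrialEnv] = None,
                 seed: int = 0,
                 verbose: bool = False) -> TrainedPolicy:
    """Learn an allocation rule by PPO over simulated trials.

    The environment defaults to the trial world with curves drawn uniformly
    from the candidate shapes.  One clipped-surrogate update (with critic
    and optional entropy regularization) happens per
    ``training.episodes_per_update`` episodes; the returned history logs the
    mean reward and mean policy entropy per update.
    """
    if training is None:
        training = TrainingConfig(metric=metric)
    elif training.metric != metric:
        training = TrainingConfig(metric=metric, episodes=training.episodes,
                                  episodes_per_update=training.episodes_per_update,
                                  hidden=training.hidden, ppo=training.ppo)
    if env is None:
        env = BatchTrialEnv(trial_config or TrialConfig(metric=metric))
    cfg = training.ppo
    rng = np.random.default_rng(seed)
    net_rng, env_rng, shuffle_rng = rng.spawn(3)

    state_dim = env.config.state_dim if hasattr(env, "config") else env.state_dim
    n_actions = env.config.K if hasattr(env, "config") else env.n_actions
    policy = PolicyNetwork(state_dim, n_actions, training.hidden, net_rng)
    critic = MLP(state_dim, training.hidden, 1, net_rng, out_scale=0.01)
    opt_pi = _Adam(policy.net.params, cfg.learning_rate)
    opt_v = _Adam(critic.params, cfg.learning_rate)

    n_updates = training.episodes // training.episodes_per_update
    E = training.episodes_per_update
    B = env.horizon
    log = []

    for upd in range(n_updates):
        # ---- rollout: E whole episodes, B decisions each -------------------
        states = np.empty((B, E, state_dim))
        actions = np.empty((B, E), dtype=int)
        logp_old = np.empty((B, E))
        s = env.reset(E, env_rng)
        for b in range(B):
            states[b] = s
            p = policy.probs(s)
            a = _sample_categorical(p, env_rng)
            actions[b] = a
            logp_old[b] = np.log(p[np.arange(E), a] + 1e-300)
            s = env.step(a)
        rewards = env.terminal_rewards(metric)
        if not np.all(np.isfinite(rewards)):
            raise FloatingPointError("non-finite reward encountered in training")

        # terminal-only reward, discount 1: the return at every decision
        # point equals the trial-end reward
        S = states.reshape(B * E, state_dim)
        A = actions.reshape(B * E)
        LP = logp_old.reshape(B * E)
        R = np.repeat(rewards[None, :], B, axis=0).reshape(B * E)
        V = critic.forward(S)[:, 0]
        adv = R - V
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)

        # ---- clipped-surrogate updates ------------------------------------
        N = B * E
        idx_all = np.arange(N)
        for _ in range(cfg.epochs):
            shuffle_rng.shuffle(idx_all)
            for start in range(0, N, cfg.minibatch):
                mb = idx_all[start:start + cfg.minibatch]
                Smb, Amb = S[mb], A[mb]
                u, cache = policy.logits(Smb, cache=True)
                p = _softmax_rows(u)
                lp = np.log(p[np.arange(len(mb)), Amb] + 1e-300)
                ratio = np.exp(lp - LP[mb])
                amb = adv[mb]
                clipped_out = ((amb > 0) & (ratio > 1 + cfg.clip)) | \
                              ((amb < 0) & (ratio < 1 - cfg.clip))
                # d(-surrogate)/d logp = -ratio*adv where the unclipped branch
                # is active, 0 where the clip zeroes the gradient
                dlp = np.where(clipped_out, 0.0, -ratio * amb) / len(mb)
                # chain rule through the softmax: d lp / d u_k = 1[k=a] - p_k
                dU = dlp[:, None] * (-p)
                dU[np.arange(len(mb)), Amb] += dlp
                if cfg.ent_coef > 0:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        lpk = np.where(p > 0, np.log(p), 0.0)
                    H = -(p * lpk).sum(axis=1, keepdims=True)
                    dU += -cfg.ent_coef * (-p * (lpk + H)) / len(mb)
                grads = policy.net.backward(cache, dU)
                opt_pi.step(policy.net.params, grads)

                v, vc = critic.forward(Smb, cache=True)
                dv = cfg.vf_coef * 2.0 * (v[:, 0] - R[mb]) / len(mb)
                gv = critic.backward(vc, dv[:, None])
                opt_v.step(critic.params, gv)

        ent = policy.entropy(S).mean()
        log.append(dict(update=upd + 1,
                        episodes=(upd + 1) * E,
                        mean_reward=float(rewards.mean()),
                        mean_entropy=float(ent)))
        if verbose:
            print(f"update {upd + 1}/{n_updates}  reward={rewards.mean():.4f}"
                  f"  entropy={ent:.3f}")

    return TrainedPolicy(policy=policy, history=pd.DataFrame(log),
                         training=training, seed=seed)


def deploy_policy(policy: PolicyNetwork | TrainedPolicy, state: np.ndarray,
                  n_block: int, rng: np.random.Generator,
                  mode: str = "sample") -> np.ndarray:
    """Turn pi(.|s) into a block allocation.

    ``sample``: n_block i.i.d. categorical draws tallied into counts (the
    deployment convention); ``round``: deterministic efficient rounding of
    the probabilities to the block size.
    """
    if isinstance(policy, TrainedPolicy):
        policy = policy.policy
    p = policy_forward(policy, state)
    if mode == "sample":
        return rng.multinomial(n_block, p)
    if mode == "round":
        return efficient_round(p, n_block)
    raise ValueError("mode must be 'sample' or 'round'")


def save_policy(trained: TrainedPolicy, path) -> None:
    """Persist network weights + run metadata as a portable .npz archive."""
    meta = dict(metric=trained.training.metric,
                episodes=trained.training.episodes,
                episodes_per_update=trained.training.episodes_per_update,
                hidden=trained.training.hidden,
                seed=trained.seed,
                state_dim=trained.policy.state_dim,
                n_actions=trained.policy.n_actions,
                **{f"ppo_{k}": v for k, v in vars(trained.training.ppo).items()})
    arrays = {f"param_{i}": p for i, p in enumerate(trained.policy.net.params)}
    np.savez(path, _meta=np.array([json.dumps(meta)]), **arrays)


def load_policy(path) -> TrainedPolicy:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["_meta"][0]))
    policy = PolicyNetwork(int(meta["state_dim"]), int(meta["n_actions"]),
                           int(meta["hidden"]))
    policy.net.params = [data[f"param_{i}"] for i in range(6)]
    ppo = PPOConfig(**{k[4:]: v for k, v in meta.items() if k.startswith("ppo_")})
    training = TrainingConfig(metric=meta["metric"], episodes=meta["episodes"],
                              episodes_per_update=meta["episodes_per_update"],
                              hidden=meta["hidden"], ppo=ppo)
    return TrainedPolicy(policy=policy, history=pd.DataFrame(),
                         training=training, seed=int(meta["seed"]))
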