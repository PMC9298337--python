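"""Block-sequential dose-finding trial: state, allocation rules, rewards.

A trial allocates N = 150 subjects over K = 5 doses.  The first N_ini = 50
go equally to the arms; the remaining subjects arrive in B = 10 blocks of
N_block = 10, each block placed by an allocation rule that sees the running
per-dose means, standard deviations, and allocation proportions.  Responses
are Gaussian around the true curve with variance 4.5.  At the end the
MCP-Mod analysis runs and all four performance metrics are scored:

* power:  dose-response detected (counts toward power only under a
  non-flat truth; under the flat truth a detection is a type I error),
* MS:     the AIC-selected family equals the true family,
* TD:     the estimated MED falls inside the true target-dose interval,
* MAE:    curve error; its reward transform is r = 1 - 2 * MAE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .dose_response import (
    DEFAULT_DELTA,
    DEFAULT_ETA,
    DEFAULT_GRID,
    DoseGrid,
    DoseResponseCurve,
    Scenario,
)
from .mcpmod import (
    AnalysisResult,
    CandidateSet,
    GroupSummary,
    analyze_trial,
    default_candidates,
)

__all__ = [
    "TrialConfig",
    "TrialState",
    "TrialRecord",
    "METRICS",
    "initialize_trial",
    "apply_block",
    "encode_state",
    "terminal_reward",
    "run_trial",
    "AllocationRule",
    "EqualAllocation",
    "FixedDesign",
    "AdaptiveOptimalAllocation",
    "RLAllocation",
]

METRICS = ("power", "MS", "TD", "MAE")


@dataclass(frozen=True)
class TrialConfig:
    grid: DoseGrid = DEFAULT_GRID
    n_total: int = 150
    n_initial: int = 50
    n_block: int = 10
    sigma2: float = 4.5          # observation-noise variance
    delta: float = DEFAULT_DELTA
    eta: float = DEFAULT_ETA
    alpha: float = 0.025
    metric: str = "MAE"

    def __post_init__(self) -> None:
        if self.n_initial % self.grid.K:
            raise ValueError("n_initial must be divisible by the number of doses")
        if (self.n_total - self.n_initial) % self.n_block:
            raise ValueError("(n_total - n_initial) must be divisible by n_block")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")

    @property
    def K(self) -> int:
        return self.grid.K

    @property
    def n_blocks(self) -> int:
        return (self.n_total - self.n_initial) // self.n_block

    @property
    def state_dim(self) -> int:
        return 3 * self.grid.K - 1


class TrialState:
    """Running per-dose responses with streaming summaries.

    Raw responses are retained because model fitting and AIC work on
    individual-level residuals.
    """

    def __init__(self, K: int):
        self.responses: list[list[float]] = [[] for _ in range(K)]
        self.n = np.zeros(K, dtype=int)
        self._sum = np.zeros(K)
        self._sumsq = np.zeros(K)

    @property
    def K(self) -> int:
        return len(self.responses)

    @property
    def n_allocated(self) -> int:
        return int(self.n.sum())

    @property
    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self._sum / self.n, np.nan)

    @property
    def sd(self) -> np.ndarray:
        """Sample SD with the n-1 denominator; 0 for groups of size < 2."""
        out = np.zeros(self.K)
        ok = self.n > 1
        m = self.mean
        ss = np.maximum(self._sumsq - self.n * m**2, 0.0)
        out[ok] = np.sqrt(ss[ok] / (self.n[ok] - 1))
        return out

    def add(self, dose_index: int, values: np.ndarray) -> None:
        values = np.atleast_1d(np.asarray(values, dtype=float))
        self.responses[dose_index].extend(values.tolist())
        self.n[dose_index] += len(values)
        self._sum[dose_index] += values.sum()
        self._sumsq[dose_index] += (values**2).sum()

    def summary(self) -> GroupSummary:
        return GroupSummary(n=self.n.copy(), mean=self.mean, sd=self.sd)


def initialize_trial(config: TrialConfig, curve: DoseResponseCurve,
                     rng: np.random.Generator) -> TrialState:
    """Equal allocation of the N_ini burn-in subjects with Gaussian noise."""
    state = TrialState(config.K)
    per_arm = config.n_initial // config.K
    sd = np.sqrt(config.sigma2)
    for k, d in enumerate(config.grid.doses):
        state.add(k, rng.normal(curve(d), sd, per_arm))
    return state


def apply_block(state: TrialState, allocation: Sequence[int],
                curve: DoseResponseCurve, config: TrialConfig,
                rng: np.random.Generator) -> TrialState:
    """Draw responses for one block of subjects and fold them in."""
    allocation = np.asarray(allocation, dtype=int)
    if allocation.sum() != config.n_block:
        raise ValueError("block allocation must sum to n_block")
    if state.n_allocated + config.n_block > config.n_total:
        raise ValueError("block would exceed the total sample size")
    sd = np.sqrt(config.sigma2)
    for k, cnt in enumerate(allocation):
        if cnt > 0:
            state.add(k, rng.normal(curve(config.grid.doses[k]), sd, cnt))
    return state


def encode_state(state: TrialState, config: TrialConfig) -> np.ndarray:
    """MDP state: (Ybar_k - Ybar_1 for k>=2, sd_1..K, n_1..K / N); length 3K-1."""
    if np.any(state.n < 2):
        raise ValueError("state encoding needs at least two subjects per dose")
    m = state.mean
    return np.concatenate([m[1:] - m[0], state.sd, state.n / config.n_total])


def terminal_reward(metric: str, analysis: AnalysisResult, scenario: Scenario,
                    config: TrialConfig) -> float:
    """Trial-end scalar reward for the configured metric, roughly in [0, 1]."""
    if metric == "power":
        return float(analysis.significant and not scenario.is_flat)
    if metric == "MS":
        return float(analysis.selected_family == scenario.family)
    if metric == "TD":
        if analysis.d_targ_hat is None or scenario.interval is None:
            return 0.0
        lo, up = scenario.interval
        return float(lo <= analysis.d_targ_hat <= up)
    if metric == "MAE":
        return 1.0 - 2.0 * analysis.mae_against(scenario.curve, config.grid)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class TrialRecord:
    scenario_id: int
    counts: np.ndarray
    analysis: AnalysisResult
    metrics: Dict[str, float]     # all four metric values for this trial
    reward: float                 # reward for config.metric
    seed: Optional[int] = None

    def to_json_dict(self) -> dict:
        return dict(scenario_id=self.scenario_id,
                    counts=self.counts.tolist(),
                    metrics=self.metrics, reward=self.reward, seed=self.seed,
                    significant=bool(self.analysis.significant),
                    selected_family=self.analysis.selected_family,
                    d_targ_hat=self.analysis.d_targ_hat)


# ---------------------------------------------------------------------------
# Allocation rules


class AllocationRule:
    """Either a fixed design (full-N counts) or a per-block policy."""

    name = "rule"

    def fixed_counts(self, config: TrialConfig) -> Optional[np.ndarray]:
        return None

    def start_trial(self, config: TrialConfig) -> None:
        """Hook for per-trial internal state (adaptive rules)."""

    def next_block(self, state: TrialState, config: TrialConfig,
                   rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class EqualAllocation(AllocationRule):
    name = "equal"

    def fixed_counts(self, config: TrialConfig) -> np.ndarray:
        if config.n_total % config.K:
            raise ValueError("equal allocation needs K | n_total")
        return np.full(config.K, config.n_total // config.K, dtype=int)


class FixedDesign(AllocationRule):
    """A predetermined apportionment of all N subjects (e.g. D-optimal 1)."""

    def __init__(self, counts: Sequence[int], name: str = "fixed"):
        self.counts = np.asarray(counts, dtype=int)
        self.name = name

    def fixed_counts(self, config: TrialConfig) -> np.ndarray:
        if self.counts.sum() != config.n_total:
            raise ValueError("fixed design counts must sum to n_total")
        return self.counts


class AdaptiveOptimalAllocation(AllocationRule):
    """Blockwise re-optimized D- or TD-optimal allocation.

    Each block: update the model probabilities from the accumulated data
    (shape parameters stay at their nominal values), minimize the criterion
    over the composition of the next block given the subjects already
    placed, and round the block weights to integer counts.
    """

    def __init__(self, criterion: str = "D",
                 candidates: Optional[CandidateSet] = None,
                 restarts: int = 3, seed: int = 0):
        if criterion not in ("D", "TD"):
            raise ValueError("criterion must be 'D' or 'TD'")
        self.criterion = criterion
        self.candidates = candidates
        self.restarts = restarts
        self.seed = seed
        self.name = f"{criterion.lower()}-optimal-2"

    def next_block(self, state: TrialState, config: TrialConfig,
                   rng: np.random.Generator) -> np.ndarray:
        from . import optimal_design as od

        cands = self.candidates or default_candidates(config.grid)
        models = od.design_models(cands)
        summary = state.summary()
        probs = od.update_model_probs(
            np.array([m.prior for m in models]), summary, models,
            sigma2=config.sigma2, grid=config.grid)
        models = tuple(
            od.NominalModel(m.family, m.theta, p) for m, p in zip(models, probs))
        if self.criterion == "D":
            obj = lambda w: od.d_objective(w, models, config.grid)
        else:
            obj = lambda w: od.td_objective(w, models, config.delta, config.grid)
        dw = od.optimize_design(obj, config.K, n_old=state.n,
                                n_new=config.n_block,
                                restarts=self.restarts, seed=self.seed,
                                maxiter=600)
        return od.efficient_round(dw.w, config.n_block)


class RLAllocation(AllocationRule):
    """Deploys a trained policy network block by block.

    ``mode='sample'`` draws each subject's dose i.i.d. from pi(k|s)
    (the deployment convention); ``mode='round'`` applies efficient rounding
    to the probabilities instead.
    """

    def __init__(self, policy, mode: str = "sample", name: str = "rl"):
        if mode not in ("sample", "round"):
            raise ValueError("mode must be 'sample' or 'round'")
        self.policy = policy
        self.mode = mode
        self.name = name

    def next_block(self, state: TrialState, config: TrialConfig,
                   rng: np.random.Generator) -> np.ndarray:
        from .rl_policy import deploy_policy

        s = encode_state(state, config)
        return deploy_policy(self.policy, s, config.n_block, rng, mode=self.mode)


def run_trial(rule: AllocationRule, scenario: Scenario, config: TrialConfig,
              rng: Optional[np.random.Generator] = None,
              seed: Optional[int] = None,
              candidates: Optional[CandidateSet] = None) -> TrialRecord:
    """Simulate one complete trial under a rule and score all four metrics.

    A master generator (from ``seed`` or ``rng``) spawns independent child
    streams for response noise and for the rule's own randomness, so records
    are a pure function of (rule, scenario, config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    noise_rng, alloc_rng = rng.spawn(2)
    cands = candidates or default_candidates(config.grid)

    fixed = rule.fixed_counts(config)
    state = TrialState(config.K)
    if fixed is not None:
        sd = np.sqrt(config.sigma2)
        for k, cnt in enumerate(fixed):
            state.add(k, noise_rng.normal(scenario.curve(config.grid.doses[k]),
                                          sd, int(cnt)))
    else:
        rule.start_trial(config)
        state = initialize_trial(config, scenario.curve, noise_rng)
        for _ in range(config.n_blocks):
            alloc = rule.next_block(state, config, alloc_rng)
            apply_block(state, alloc, scenario.curve, config, noise_rng)

    analysis = analyze_trial(state.summary(), cands, alpha=config.alpha,
                             delta=config.delta, grid=config.grid)
    metrics = {m: terminal_reward(m, analysis, scenario, config) for m in METRICS}
    metrics["MAE"] = analysis.mae_against(scenario.curve, config.grid)
    # the power *metric* records detection even under the flat truth
    metrics["power"] = float(analysis.significant)
    rewards_metric = config.metric
    reward = (1.0 - 2.0 * metrics["MAE"] if rewards_metric == "MAE"
              else terminal_reward(rewards_metric, analysis, scenario, config))
    return TrialRecord(scenario_id=scenario.id, counts=state.n.copy(),
                       analysis=analysis, metrics=metrics, reward=reward,
                       seed=seed)
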