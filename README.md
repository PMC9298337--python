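# adadose

Adaptive subject allocation for phase II dose-response (dose-finding)
trials: a complete simulation/analysis stack for comparing allocation rules
— equal, model-averaged D-/TD-optimal (fixed and blockwise-adaptive), and
reinforcement-learned rules trained to directly optimize a trial-level
performance metric.

## Who this is for

Trial statisticians and methodologists studying phase II dose-ranging
designs under the MCP-Mod analysis framework.  The package simulates a
K = 5 arm trial on doses (0, 2, 4, 6, 8) mg with N = 150 subjects, a
Gaussian endpoint with noise variance σ² = 4.5, and a clinically relevant
effect δ = 1.3 over placebo, and asks: *how should the 100 subjects after
the equal burn-in of 50 be allocated across arms to maximize what you
actually care about?*

## The model and metrics

True mean responses follow μ(d) = e₀ + scale·f(d; shape) from one of six
families (linear, Emax, sigmoid Emax, quadratic, exponential, flat), each
calibrated so max₍d∈[0,8]₎ μ(d) − μ(0) equals a prescribed maximum effect.
The end-of-trial analysis is MCP-Mod:

1. **MCP step** — a maximum of optimal-contrast t statistics
   T_m = c_mᵀȲ / (σ̂·√(Σ_k c²_mk/n_k)) is referred to its one-sided
   multivariate-t null distribution (candidate set: linear, Emax with
   ED50 = 0.79, sigEmax with ED50 = 4 and Hill = 5; α = 0.025 one-sided).
2. **Mod step** — candidates are fitted by least squares, one is selected
   by AIC, and the minimum effective dose
   d̂ = argmin_d { μ̂(d) ≥ μ̂(0) + δ } is read off the fitted curve.

Four trial-level metrics are scored: **power** (dose-response detected;
type I error under the flat truth), **MS** (correct family selected),
**TD** (d̂ inside the true target-dose interval I(η = 0.1)), and **MAE**
(mean absolute error of the placebo-shifted fitted curve at the active
doses, reward transform r = 1 − 2·MAE).

Allocation rules:

* **Equal** — 30 subjects per arm.
* **D-optimal** — minimize −Σ_m (p_m/k_m)·log det M_m(w) over the simplex
  (M_m the Fisher information, p_m the model probability, k_m the
  parameter count); **TD-optimal** — minimize Σ_m p_m·log v_m(w) with v_m
  the asymptotic variance of the estimated target dose.  Both come in a
  fixed (computed up front, efficiently rounded to integers) and an
  adaptive variant (re-optimized every 10-subject block with
  model probabilities re-learned from the accumulated data).
* **RL** — a softmax policy network π(k|s) (two 256-unit ReLU layers) over
  a 14-dimensional summary state (placebo-differences of arm means, arm
  SDs, allocation proportions), trained by proximal policy optimization
  against whole simulated trials with terminal-only reward equal to the
  chosen metric.

## Worked example

Design criteria and their integer apportionments:

```text
$ adadose design --criterion D
criterion: D-optimal, N=150, delta=1.3
weights: 0.2973 0.1999 0.1158 0.0921 0.2947
counts:  44 30 18 14 44

$ adadose design --criterion TD
criterion: TD-optimal, N=150, delta=1.3
weights: 0.3055 0.2631 0.1150 0.1771 0.1392
counts:  46 39 17 27 21
```

The D-optimal design loads the placebo and top arms (information about
curvature lives at the extremes); the TD-optimal design shifts mass to the
low-dose region where the candidate MEDs sit.

Evaluating equal allocation on the three candidate scenarios (400
simulated trials each):

```python
import adadose as ad

scen = ad.build_scenario_table()          # the 16 true scenarios
cfg = ad.TrialConfig()                    # N=150, blocks of 10, sigma2=4.5
df = ad.evaluate_rule(ad.EqualAllocation(),
                      [scen[0], scen[3], scen[6]], 400, cfg, seed=1)
print(df[["scenario", "family", "power", "MS", "TD", "MAE"]].round(3))
```

```text
 scenario  family  power    MS    TD   MAE
        1  linear  0.908 0.842 0.252 0.283
        4    emax  0.930 0.712 0.200 0.427
        7 sigemax  0.988 0.268 0.190 0.354
```

Power is high for all candidate truths; the sigEmax family is hard to
identify from equal allocation (MS = 0.27), and the continuous MED lands
in its ±10% target band only ~20% of the time — the headroom the adaptive
rules go after.  Training and deploying an RL rule:

```python
from adadose import RLAllocation, TrialConfig, train_policy

trained = train_policy(metric="MAE", trial_config=TrialConfig(metric="MAE"),
                       seed=0)             # 1e6 episodes by default
rule = RLAllocation(trained)
df = ad.evaluate_rule(rule, scen, 10_000, cfg, seed=1)
```

(Use `adadose train --metric MAE --episodes 20000 --checkpoint pol.npz`
for a quick reduced-scale run; at that scale the learned rule already
lowers the mean candidate-scenario MAE from ≈0.37 to ≈0.30.)  Because
adaptive allocation can distort the test's null distribution,
`adadose.adjust_significance` recalibrates α from the empirical p-value
distribution under the flat scenario before a final evaluation sweep.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes from scratch, end to end: the target doses of five calibrated
scenario curves at δ = 1.3 plus two off-nominal effect sizes (bisection on
μ(d) − μ(0) = δ), the model-averaged D- and TD-optimal weights over the
dose simplex with their Pukelsheim–Rieder roundings at N = 150, and the
Monte-Carlo type-I error of the multiple contrast test under the flat
scenario with equal allocation (2000 simulated trials).  Results are
written as JSON keyed by target id.
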