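# Methods

This note records the modelling and numerical choices behind `adadose`,
what the simulated world does and does not capture, and the known
limitations of each component.

## Trial world

A single-endpoint, parallel-arm phase II trial on the fixed grid
(0, 2, 4, 6, 8) mg.  Defaults (all in `TrialConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_total` | 150 | total subjects |
| `n_initial` | 50 | equal burn-in (10 per arm) |
| `n_block` | 10 | subjects per adaptive block (B = 10 blocks) |
| `sigma2` | 4.5 | Gaussian noise variance (response units²) |
| `delta` | 1.3 | clinically relevant effect over placebo |
| `eta` | 0.1 | half-width of the relative target-effect band |
| `alpha` | 0.025 | one-sided significance level |

Responses are i.i.d. Normal(μ(d_k), σ²) — no dropout, covariates, delayed
response, or heteroscedasticity.  A green simulation result therefore
establishes behaviour under exactly this homoscedastic-Gaussian,
immediate-response world, not robustness to operational complications.

## Dose-response curves and calibration

Each family is written μ(d) = e₀ + scale·f(d; shape) with a standardized
shape f (f(0) = 0): linear f = d; Emax f = d/(ED50+d); sigmoid Emax
f = dʰ/(ED50ʰ+dʰ); quadratic f = d(2v−d)/v² (vertex v); exponential
f = exp(d/τ)−1; flat f = 0.  Calibration solves for `scale` so that the
maximum of μ(d)−μ(0) over the dose range equals the prescribed maximum
effect — at the top dose for monotone families, at the vertex for the
quadratic.  Parameters are kept at full precision: the 2–3 significant
digits one would print for such coefficients (e.g. 1.81 for the Emax
scale, whose exact value is 1.8129375) are not accurate enough to
reproduce target doses to 0.01 mg.

The scenario table holds five families × three maximum effects
(1.65, 1.65×0.8, 1.65×1.2) plus a flat scenario for the type I error; the
three shapes at maximum effect 1.65 (linear; Emax ED50 = 0.79; sigEmax
ED50 = 4, Hill = 5) double as the MCP-Mod candidate set with prior 1/3
each.

**Target dose.** d_targ = argmin_d {μ(d) ≥ μ(0)+δ} is found by a coarse
512-point scan for the first upcrossing followed by Brent refinement to
1e-9 mg.  The scan-then-refine scheme handles the non-monotone quadratic
family without case analysis.  The target-dose interval takes the target
doses of δ(1−η) and δ(1+η); a missing or out-of-range upper end is clipped
to the top dose, and the interval is undefined when even δ(1−η) is
unreachable (then a TD "hit" is impossible by definition).

## MCP-Mod analysis

**Contrasts.** For candidate mean vector μ_m and S = diag(1/n_k), the
power-optimal contrast ∝ S⁻¹(μ_m − μ̄1) (μ̄ the S⁻¹-weighted grand mean),
normalized to unit length.  **Test.** The max-T statistic is referred to
the one-sided M-variate t distribution with ν = N−K degrees of freedom and
the contrast-induced correlation; orthant probabilities come from SciPy's
quasi-Monte-Carlo integrator with a fixed internal seed, so p-values are
reproducible to the QMC tolerance (~1e-4).  A multivariate *t* (rather
than normal) reference was chosen because the pooled variance is
estimated; at ν = 145 the difference is small but systematically in the
conservative direction.

**Fitting.** Model means are constant within arms, so individual-level
least squares reduces exactly to weighted least squares on arm means plus
a fit-independent within-arm residual term.  Shape parameters are profiled
(closed-form WLS in e₀ and scale at each candidate shape) over a coarse
grid — 30 log-spaced ED50 values for Emax; 24 ED50 × 7 Hill values for
sigEmax — then polished by bounded trust-region least squares
(ED50 ∈ [0.001, 1.5]·d_max, Hill ∈ [0.5, 10]).  The grid start makes the
polish basin reliable; a `polish=False` mode keeps the grid solution and
is used by the vectorized training kernels (see below).  Non-convergence
returns the best-found parameters flagged rather than raising.

**Selection.** AIC = n·log(RSS/n) + 2(p+1), p mean-structure parameters
(+1 for σ²); ties break to fewer parameters, then candidate order.  By
default selection formally uses all candidates regardless of test
significance — the convention under which the performance metrics are
evaluated — with an opt-in `restrict_to_significant` mode.  The estimated
MED is continuous (never rounded to a grid dose).

## Optimal designs

Unit-variance Fisher information M_m(w) = Σ_k w_k g_m(d_k)g_m(d_k)ᵀ with
analytic gradients g_m = ∂μ/∂θ.  The model-averaged D-criterion uses the
per-parameter normalization p_m/k_m on the log-determinants, which is what
makes the criterion comparable across families of different dimension.
The TD-criterion averages log v_m, v_m = b_mᵀM_m(w)⁻b_m, where b_m comes
from implicit differentiation of μ(d;θ)−μ(0;θ) = δ at the nominal target
dose; the generalized inverse uses an eigendecomposition with a 1e-10
relative cutoff and an explicit estimability check (b outside the range of
M ⇒ +∞, e.g. all mass on placebo).

Optimization over the simplex uses a softmax reparameterization and
Nelder-Mead from 20 seeded restarts (first start = uniform design);
objective tolerance 1e-8.  The problem is 5-dimensional and smooth, and
independent seeds agree to 1e-4 in the weights.  The blockwise-adaptive
variant optimizes only the composition of the next block given the
subjects already placed, with fewer restarts and a tighter iteration cap
(the objective landscape near an interior incumbent is benign).

**Rounding.** Pukelsheim-Rieder efficient apportionment: start at
⌈(N−S/2)w_k⌉ and repair one subject at a time — decrement the arm
maximizing (n_k−1)/w_k, increment the arm minimizing n_k/w_k — preserving
the efficiency objective min_k n_k/w_k (verified against exhaustive search
for small K, N).

**Model-probability updates.** Between blocks the model weights are
recomputed as posterior ∝ prior × exp(−RSS_m/2σ²), with RSS_m minimized
over (e₀, scale) only (shapes fixed at nominal) and σ² the known noise
variance.  This is the normalized maximized-likelihood update; a fully
Bayesian update with parameter priors would differ mainly by an Occam
factor that is common across these similarly-sized models.  Recomputing
from the full accumulated data each block (rather than chaining block
posteriors) keeps the update order-independent.

## Reinforcement learning

**State** (dimension 3K−1 = 14): placebo-differences of arm means, arm
SDs (n−1 denominator), allocation proportions n_k/N.  **Action** during
training: the whole next block goes to one dose — this collapses the
per-block action space from compositions of 10 into 5 categories and
substantially stabilizes learning.  **Reward**: terminal-only, the chosen
metric transformed to ≈[0,1] (r = 1−2·MAE may dip below 0 for very bad
fits and is deliberately not clipped).  Discount 1.0 — the horizon is a
fixed 10 decisions and the objective is the undiscounted trial-end metric.

The policy is a 14→256→256→5 ReLU network with softmax head; the critic
is a separate network of the same size.  PPO uses the clipped surrogate
(clip 0.2), advantage = return − critic baseline, batch-normalized
advantages, Adam at 3e-4 for both networks, 10 epochs of minibatch 1000
per update, one update per 1000 episodes, entropy coefficient 0.  These
are conventional policy-gradient settings; since no deep-RL framework is
a dependency, the forward/backward passes and Adam are implemented
directly in NumPy, which makes training bit-reproducible from one integer
seed.  The final layer is initialized near zero so the initial policy is
near-uniform (≈ equal allocation): early training is therefore anchored
at the equal-allocation operating point and cannot start out pathological.

Training curves are drawn uniformly from the candidate shapes at maximum
effect 1.65 (an optional scenario list can add, e.g., the exponential
family, which is known to be the adversarial case for candidate-trained
rules).  The production scale is 1e6 episodes; reduced-scale runs
(2e4 episodes, minutes on one CPU) already show metric improvements over
equal allocation but are not converged — the test suite uses them for
non-inferiority checks, not for reproducing converged performance levels.

**Training-time analysis kernels.** Rewards for MS/TD/MAE need a model
fit per episode; the training path uses a fully vectorized grid-profile
fit (identical profile grids, no polish) and closed-form MED inversion,
several hundred times faster than per-trial fitting.  The power reward
needs the max-T decision; critical values are memoized on the
allocation-count vector, which takes only ~1000 distinct values under
block-wise single-dose actions.  The batch kernels are cross-checked
against the reference per-trial analysis in the test suite.

**Deployment** samples each of the 10 subjects i.i.d. from π(k|s)
(multinomial), with a deterministic efficient-rounding mode as an
alternative.

## Evaluation and type-I control

Sweeps average the four metrics over independent trials, with per-scenario
seeds derived from a master seed so rule comparisons share random worlds
where possible.  MS/TD/MAE are reported both unconditionally and
conditioned on test significance.  Because adaptive rules can make the
null p-value distribution anticonservative, `adjust_significance`
simulates the flat scenario and returns the target quantile of the
trial-level minimum adjusted p-value; the recalibrated threshold should be
estimated on an independent batch from the final evaluation (selection
bias otherwise leaks into the reported type-I error).

## Known limitations

* The PPO implementation is single-threaded NumPy; a 1e6-episode
  production run takes hours, not minutes.
* Nonlinear shape parameters are bounded (ED50 ≤ 1.5·d_max, Hill ≤ 10);
  fits on data truly generated outside these ranges are clipped to the
  boundary — intentional regularization, but a bias under gross
  misspecification.
* The multivariate-t orthant probabilities are QMC estimates; p-values
  carry ~1e-4 integration noise (fixed seed, so deterministic).
* Only Gaussian endpoints with known-variance model-probability updates
  are implemented; binary endpoints and early stopping are out of scope.
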