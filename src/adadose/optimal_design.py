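"""Model-averaged D- and TD-optimal allocation over a fixed dose grid.

Approximate designs are probability vectors w over the K doses.  With
homoscedastic Gaussian responses the (unit-variance) Fisher information of
model m is M_m(w) = sum_k w_k g_m(d_k) g_m(d_k)', g_m the gradient of the
mean function in its parameters at the nominal values.

Two averaged criteria are minimized over the simplex:

* D:   - sum_m (p_m / k_m) log det M_m(w)      (per-parameter normalization)
* TD:    sum_m  p_m log v_m(w),  v_m = b_m' M_m(w)^- b_m

where b_m is the sensitivity of the minimum effective dose to the model
parameters (implicit differentiation of mu(d) - mu(0) = delta) and the
quadratic form uses a generalized inverse with an estimability check.

Continuous weights are converted into integer subject counts by the
Pukelsheim-Rieder efficient apportionment, and both criteria support an
adaptive (blockwise) mode where already-allocated subjects are fixed and
only the next block is optimized.  Model weights can be re-learned between
blocks from the accumulated data (normalized maximized-likelihood update
with shape parameters held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .dose_response import DEFAULT_DELTA, DEFAULT_GRID, DoseGrid, target_dose
from .mcpmod import CandidateSet, GroupSummary, _wls_profile

__all__ = [
    "NominalModel",
    "DesignWeights",
    "design_models",
    "model_gradient",
    "fisher_information",
    "d_objective",
    "td_variance",
    "td_objective",
    "optimize_design",
    "efficient_round",
    "update_model_probs",
]

_PARAM_COUNT = {"linear": 2, "emax": 3, "sigemax": 4}


@dataclass(frozen=True)
class NominalModel:
    """A candidate family at its nominal (calibrated) parameter values.

    theta stacks (e0, scale, *shape); k is the parameter count used by the
    per-parameter D-criterion normalization.
    """

    family: str
    theta: Tuple[float, ...]
    prior: float

    @property
    def k(self) -> int:
        return _PARAM_COUNT[self.family]

    def mu(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        e0, scale, *shape = self.theta
        if self.family == "linear":
            return e0 + scale * d
        if self.family == "emax":
            (ed50,) = shape
            return e0 + scale * d / (ed50 + d)
        if self.family == "sigemax":
            ed50, h = shape
            with np.errstate(divide="ignore", invalid="ignore"):
                dh = np.where(d > 0, d**h, 0.0)
            return e0 + scale * dh / (ed50**h + dh)
        raise ValueError(self.family)

    def dmu_dd(self, d: float) -> float:
        """Analytic derivative of the mean in the dose."""
        e0, scale, *shape = self.theta
        if self.family == "linear":
            return scale
        if self.family == "emax":
            (ed50,) = shape
            return scale * ed50 / (ed50 + d) ** 2
        if self.family == "sigemax":
            ed50, h = shape
            if d <= 0:
                return 0.0
            return scale * h * ed50**h * d ** (h - 1) / (ed50**h + d**h) ** 2
        raise ValueError(self.family)


def design_models(candidates: CandidateSet) -> Tuple[NominalModel, ...]:
    """Nominal design models from an MCP-Mod candidate set."""
    return tuple(
        NominalModel(family=m.family,
                     theta=(m.curve.e0, m.curve.scale, *m.curve.shape),
                     prior=m.prior)
        for m in candidates.models
    )


def model_gradient(model: NominalModel, d: float) -> np.ndarray:
    """Gradient of the mean function in theta = (e0, scale, *shape) at d."""
    e0, scale, *shape = model.theta
    if model.family == "linear":
        return np.array([1.0, d])
    if model.family == "emax":
        (ed50,) = shape
        return np.array([1.0, d / (ed50 + d), -scale * d / (ed50 + d) ** 2])
    if model.family == "sigemax":
        ed50, h = shape
        if d <= 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        dh, edh = d**h, ed50**h
        den = (edh + dh) ** 2
        return np.array([
            1.0,
            dh / (edh + dh),
            -scale * dh * h * ed50 ** (h - 1) / den,
            scale * edh * dh * (np.log(d) - np.log(ed50)) / den,
        ])
    raise ValueError(f"no gradient for family {model.family!r}")


@lru_cache(maxsize=128)
def _gradient_matrix(model: NominalModel, grid: DoseGrid) -> np.ndarray:
    """(K, k_m) stacked parameter gradients at the grid doses (cached:
    design optimizers evaluate the criterion thousands of times)."""
    return np.stack([model_gradient(model, d) for d in grid.doses])


def fisher_information(model: NominalModel, w: np.ndarray,
                       grid: DoseGrid = DEFAULT_GRID) -> np.ndarray:
    """Unit-variance information M = sum_k w_k g(d_k) g(d_k)'."""
    G = _gradient_matrix(model, grid)
    return G.T @ (G * np.asarray(w, dtype=float)[:, None])


def d_objective(w: np.ndarray, models: Sequence[NominalModel],
                grid: DoseGrid = DEFAULT_GRID) -> float:
    """Model-averaged D-criterion, - sum_m (p_m/k_m) log det M_m(w).

    Lower is better; +inf when any model's information is singular (design
    supported on too few doses)."""
    total = 0.0
    for m in models:
        sign, logdet = np.linalg.slogdet(fisher_information(m, w, grid))
        if sign <= 0:
            return np.inf
        total -= m.prior / m.k * logdet
    return total


@lru_cache(maxsize=128)
def _td_gradient(model: NominalModel, delta: float, grid: DoseGrid) -> np.ndarray:
    """Sensitivity b = d(d_targ)/d(theta) by implicit differentiation.

    With g(d, theta) = mu(d; theta) - mu(0; theta) - delta = 0 at the target
    dose, b_j = -(dg/dtheta_j)/(dg/dd).  The placebo component cancels, so
    b has a zero e0 entry.
    """
    from .dose_response import DoseResponseCurve  # local, avoids cycle noise

    e0, scale, *shape = model.theta
    curve = DoseResponseCurve(model.family, e0=e0, scale=scale, shape=tuple(shape))
    d0 = target_dose(curve, delta, grid)
    if d0 is None:
        raise ValueError(f"nominal {model.family} model never reaches delta={delta}")
    dg_dtheta = model_gradient(model, d0) - model_gradient(model, 0.0)
    dg_dd = model.dmu_dd(d0)
    return -dg_dtheta / dg_dd


def td_variance(model: NominalModel, w: np.ndarray,
                delta: float = DEFAULT_DELTA,
                grid: DoseGrid = DEFAULT_GRID) -> float:
    """v_m = b' M(w)^- b, proportional to the asymptotic MED variance.

    Uses an eigendecomposition-based generalized inverse; +inf when b is not
    in the range of M (the target dose is not estimable under w, e.g. all
    mass on placebo)."""
    b = _td_gradient(model, delta, grid)
    M = fisher_information(model, w, grid)
    vals, vecs = np.linalg.eigh(M)
    tol = 1e-10 * max(vals.max(), 1.0)
    keep = vals > tol
    proj = vecs[:, ~keep].T @ b
    if np.any(np.abs(proj) > 1e-8 * max(np.linalg.norm(b), 1.0)):
        return np.inf
    coeff = vecs[:, keep].T @ b
    return float(np.sum(coeff**2 / vals[keep]))


def td_objective(w: np.ndarray, models: Sequence[NominalModel],
                 delta: float = DEFAULT_DELTA,
                 grid: DoseGrid = DEFAULT_GRID) -> float:
    """Averaged TD-criterion, sum_m p_m log v_m(w); lower is better."""
    total = 0.0
    for m in models:
        v = td_variance(m, w, delta, grid)
        if not np.isfinite(v) or v <= 0:
            return np.inf
        total += m.prior * np.log(v)
    return total


@dataclass
class DesignWeights:
    """Continuous allocation proportions with an integer apportionment."""

    w: np.ndarray
    rounded: Optional[np.ndarray] = None
    objective: float = np.nan

    def round_to(self, n_total: int) -> np.ndarray:
        self.rounded = efficient_round(self.w, n_total)
        return self.rounded


def optimize_design(objective: Callable[[np.ndarray], float],
                    K: int,
                    n_old: Optional[np.ndarray] = None,
                    n_new: Optional[int] = None,
                    restarts: int = 20,
                    seed: int = 0,
                    tol: float = 1e-8,
                    maxiter: int = 2000) -> DesignWeights:
    """Minimize a design criterion over the K-simplex.

    Softmax reparameterization with Nelder-Mead from ``restarts`` seeded
    starts (the first at the uniform design).  In the adaptive mode
    (``n_old``/``n_new`` given) the block composition u is optimized and the
    objective is evaluated at the effective weights
    (n_old + n_new u) / (sum n_old + n_new); the returned ``w`` is u, i.e.
    the allocation of the new block.
    """
    adaptive = n_old is not None
    if adaptive:
        n_old = np.asarray(n_old, dtype=float)
        total = n_old.sum() + n_new

        def wrapped(u):
            return objective((n_old + n_new * u) / total)
    else:
        wrapped = objective

    def from_logits(x):
        e = np.exp(x - x.max())
        return e / e.sum()

    rng = np.random.default_rng(seed)
    best_x, best_f = None, np.inf
    for r in range(restarts):
        x0 = np.zeros(K) if r == 0 else rng.normal(0.0, 1.5, K)
        res = minimize(lambda x: wrapped(from_logits(x)), x0,
                       method="Nelder-Mead",
                       options=dict(maxiter=maxiter, xatol=1e-6, fatol=tol))
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("design optimization failed from all restarts")
    return DesignWeights(w=from_logits(best_x), objective=float(best_f))


def efficient_round(w: np.ndarray, n_total: int) -> np.ndarray:
    """Pukelsheim-Rieder efficient apportionment of weights into counts.

    Start from n_k = ceil((N - S/2) w_k) over the S support points, then
    adjust one subject at a time: decrement the support point maximizing
    (n_k - 1) / w_k, or increment the one minimizing n_k / w_k, until the
    counts sum to N; this preserves the efficiency objective min_k n_k/w_k.
    Ties break to the lowest dose index.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    support = w > 0
    S = int(support.sum())
    n = np.zeros(len(w), dtype=int)
    n[support] = np.ceil((n_total - S / 2) * w[support] - 1e-12).astype(int)
    while n.sum() > n_total:
        ratio = np.where(support, (n - 1) / np.where(support, w, 1.0), -np.inf)
        n[int(np.argmax(ratio))] -= 1
    while n.sum() < n_total:
        ratio = np.where(support, n / np.where(support, w, 1.0), np.inf)
        n[int(np.argmin(ratio))] += 1
    return n


def update_model_probs(priors: np.ndarray, summary: GroupSummary,
                       models: Sequence[NominalModel],
                       sigma2: float,
                       grid: DoseGrid = DEFAULT_GRID) -> np.ndarray:
    """Blockwise model-probability update from interim data.

    Posterior p_m proportional to prior times the maximized Gaussian
    likelihood of model m with only the location/scale (e0, scale) free and
    the shape parameters fixed at their nominal values, noise variance
    ``sigma2`` known: log L_m = -RSS_m / (2 sigma2) up to a shared constant.
    Normalization happens in log space.
    """
    priors = np.asarray(priors, dtype=float)
    if summary.n.sum() == 0:
        return priors / priors.sum()
    d = grid.array()
    loglik = np.empty(len(models))
    for i, m in enumerate(models):
        e0, scale, *shape = m.theta
        f = (m.mu(d) - e0) / scale  # standardized shape at fixed parameters
        _, _, rss = _wls_profile(f[None, :], summary.n, summary.mean)
        loglik[i] = -(float(rss[0]) + summary.rss_within) / (2.0 * sigma2)
    logpost = np.log(priors) + loglik
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()
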