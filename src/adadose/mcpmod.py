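"""End-of-trial MCP-Mod analysis for the simulated dose-finding trial.

The MCP step tests for any dose-response signal with a maximum of optimal
single-contrast t statistics, one contrast per candidate shape, against the
one-sided multivariate-t reference distribution implied by the contrasts and
the per-dose sample sizes.  The Mod step fits each candidate family to the
data by least squares, selects a model by AIC, and reads the minimum
effective dose and curve-level error off the fitted curve.

The default candidate set holds the three shapes prespecified for the trial:
linear, Emax (ED50 = 0.79) and sigmoid Emax (ED50 = 4, Hill = 5), each
calibrated to a maximum effect of 1.65 over [0, 8] mg and carrying prior
weight 1/3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import brentq, least_squares

from .dose_response import (
    DEFAULT_DELTA,
    DEFAULT_GRID,
    DoseGrid,
    DoseResponseCurve,
    calibrate_curve,
    target_dose,
)

__all__ = [
    "CandidateModel",
    "CandidateSet",
    "default_candidates",
    "GroupSummary",
    "TestResult",
    "FitResult",
    "AnalysisResult",
    "optimal_contrasts",
    "mct_test",
    "critical_value",
    "fit_candidate",
    "select_model",
    "estimate_target_dose",
    "compute_mae",
    "analyze_trial",
]

# internal seed for the quasi-Monte-Carlo multivariate-t integrations; fixed
# so p-values are reproducible across calls
_MVT_SEED = 20210924


@dataclass(frozen=True)
class CandidateModel:
    family: str
    shape: Tuple[float, ...]
    prior: float
    curve: DoseResponseCurve

    def mean_vector(self, grid: DoseGrid) -> np.ndarray:
        return np.asarray(self.curve(grid.array()), dtype=float)


@dataclass(frozen=True)
class CandidateSet:
    models: Tuple[CandidateModel, ...]

    def __post_init__(self) -> None:
        if abs(sum(m.prior for m in self.models) - 1.0) > 1e-9:
            raise ValueError("candidate prior probabilities must sum to 1")

    @property
    def M(self) -> int:
        return len(self.models)

    def mean_matrix(self, grid: DoseGrid) -> np.ndarray:
        """(M, K) candidate mean vectors at the grid doses."""
        return np.stack([m.mean_vector(grid) for m in self.models])

    @property
    def families(self) -> Tuple[str, ...]:
        return tuple(m.family for m in self.models)


def default_candidates(grid: DoseGrid = DEFAULT_GRID,
                       max_effect: float = 1.65) -> CandidateSet:
    """Prespecified candidates: linear, Emax(0.79), sigEmax(4, 5), priors 1/3."""
    specs = (("linear", ()), ("emax", (0.79,)), ("sigemax", (4.0, 5.0)))
    models = tuple(
        CandidateModel(family=f, shape=s, prior=1.0 / 3.0,
                       curve=calibrate_curve(f, s, max_effect, grid))
        for f, s in specs
    )
    return CandidateSet(models)


@dataclass
class GroupSummary:
    """Per-dose sufficient statistics of a completed (or interim) trial."""

    n: np.ndarray          # subjects per dose
    mean: np.ndarray       # response means per dose
    sd: np.ndarray         # sample SDs per dose (n-1 denominator)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)

    @classmethod
    def from_responses(cls, responses: Sequence[np.ndarray]) -> "GroupSummary":
        n = np.array([len(r) for r in responses])
        mean = np.array([np.mean(r) if len(r) else np.nan for r in responses])
        sd = np.array([np.std(r, ddof=1) if len(r) > 1 else 0.0 for r in responses])
        return cls(n=n, mean=mean, sd=sd)

    @property
    def K(self) -> int:
        return len(self.n)

    @property
    def df(self) -> int:
        """Pooled-variance degrees of freedom, sum n_k - K."""
        return int(self.n.sum() - self.K)

    @property
    def rss_within(self) -> float:
        """Within-group residual sum of squares."""
        return float(np.sum((self.n - 1) * self.sd**2))

    @property
    def sigma2_pooled(self) -> float:
        if self.df < 1:
            raise ValueError("pooled variance needs sum(n) > K")
        return self.rss_within / self.df


def optimal_contrasts(means: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Power-optimal contrast per candidate mean vector.

    For candidate mean vector mu and covariance S = diag(1/n_k) the contrast
    maximizing the noncentrality c'mu / sqrt(c'Sc) is proportional to
    S^{-1}(mu - mubar 1) with mubar the S^{-1}-weighted grand mean.  Columns
    are normalized to unit Euclidean length, sign fixed so c'mu > 0.

    Returns a (K, M) matrix; columns sum to zero.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("all group sizes must be >= 1")
    C = np.empty((means.shape[1], means.shape[0]))
    for m, mu in enumerate(means):
        if np.ptp(mu) == 0:
            raise ValueError("constant candidate mean vector admits no contrast")
        mubar = np.sum(n * mu) / np.sum(n)
        c = n * (mu - mubar)
        c /= np.linalg.norm(c)
        if c @ mu < 0:
            c = -c
        C[:, m] = c
    return C


@dataclass
class TestResult:
    contrasts: np.ndarray            # (K, M)
    tstats: np.ndarray               # (M,)
    min_pvalue: float                # adjusted p-value of the max statistic
    significant: bool
    alpha: float
    pvalues: Optional[np.ndarray] = None   # per-model adjusted p-values
    df: int = 0


def _contrast_correlation(C: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of the contrast statistics and per-contrast variances c'Sc."""
    Sinv = 1.0 / np.asarray(n, dtype=float)
    A = C.T @ (C * Sinv[:, None])
    v = np.diag(A).copy()
    R = A / np.sqrt(np.outer(v, v))
    return R, v


def _mvt_cdf(q: np.ndarray, R: np.ndarray, df: int) -> float:
    dist = stats.multivariate_t(shape=R, df=df, allow_singular=True)
    return float(dist.cdf(q, random_state=np.random.default_rng(_MVT_SEED)))


def critical_value(C: np.ndarray, n: np.ndarray, df: int,
                   alpha: float = 0.025) -> float:
    """One-sided level-alpha quantile of max_m T_m under the null.

    T is M-variate t with the contrast-induced correlation; for M = 1 this
    reduces to the univariate t quantile.
    """
    R, _ = _contrast_correlation(C, n)
    M = R.shape[0]
    if M == 1:
        return float(stats.t.ppf(1 - alpha, df))
    lo = float(stats.t.ppf(1 - alpha, df))      # Bonferroni bounds bracket
    hi = float(stats.t.ppf(1 - alpha / M, df))
    f = lambda q: _mvt_cdf(np.full(M, q), R, df) - (1 - alpha)
    if f(lo) > 0:
        return lo
    return float(brentq(f, lo, hi + 0.5, xtol=1e-5))


def mct_test(summary: GroupSummary, candidates: CandidateSet,
             alpha: float = 0.025, grid: DoseGrid = DEFAULT_GRID,
             per_model_pvalues: bool = False) -> TestResult:
    """Max-T multiple contrast test for a dose-response signal.

    T_m = c_m' Ybar / (sigma_hat sqrt(sum c_mk^2 / n_k)); the trial is
    significant when the adjusted p-value of max_m T_m falls below ``alpha``.
    Per-model adjusted p-values are optional (they cost one quasi-Monte-Carlo
    integration each).
    """
    if summary.df < 1:
        raise ValueError("need residual degrees of freedom >= 1")
    C = optimal_contrasts(candidates.mean_matrix(grid), summary.n)
    R, v = _contrast_correlation(C, summary.n)
    sigma = np.sqrt(summary.sigma2_pooled)
    tstats = (C.T @ summary.mean) / (sigma * np.sqrt(v))
    tmax = float(np.max(tstats))
    minp = 1.0 - _mvt_cdf(np.full(len(tstats), tmax), R, summary.df)
    pvals = None
    if per_model_pvalues:
        pvals = np.array([
            1.0 - _mvt_cdf(np.full(len(tstats), t), R, summary.df)
            for t in tstats
        ])
    return TestResult(contrasts=C, tstats=tstats, min_pvalue=minp,
                      significant=minp <= alpha, alpha=alpha,
                      pvalues=pvals, df=summary.df)


# ---------------------------------------------------------------------------
# Mod step: candidate fitting and selection

#: number of mean-structure parameters per family
_N_PARAMS = {"linear": 2, "emax": 3, "sigemax": 4}

# ED50 search window relative to the top dose and Hill bounds; these mirror
# common dose-finding practice and keep the sigEmax fit identified
_ED50_REL_BOUNDS = (0.001, 1.5)
_HILL_BOUNDS = (0.5, 10.0)


def _wls_profile(F: np.ndarray, n: np.ndarray, ybar: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form weighted LS of ybar on [1, f] for a batch of shapes.

    F is (G, K); returns (e0, scale, rss) arrays over the G shape candidates,
    with weights n_k (so rss is the group-level weighted RSS).
    """
    w = np.asarray(n, dtype=float)
    W = w.sum()
    Sf = F @ w
    Sff = (F * F) @ w
    Sy = float(ybar @ w)
    Sfy = F @ (w * ybar)
    det = W * Sff - Sf**2
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(np.abs(det) > 1e-300, (W * Sfy - Sf * Sy) / det, 0.0)
    e0 = (Sy - scale * Sf) / W
    resid = ybar[None, :] - e0[:, None] - scale[:, None] * F
    rss = (resid**2) @ w
    return e0, scale, rss


@dataclass
class FitResult:
    family: str
    e0: float
    scale: float
    shape: Tuple[float, ...]
    rss: float                 # individual-level residual sum of squares
    aic: float
    curve: DoseResponseCurve
    converged: bool = True

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]


def fit_candidate(summary: GroupSummary, family: str,
                  grid: DoseGrid = DEFAULT_GRID, polish: bool = True) -> FitResult:
    """Least-squares fit of one candidate family to the trial data.

    Since the model mean is constant within a dose group, the fit only needs
    the group sizes and means: the individual-level RSS equals the weighted
    group-mean RSS plus the (fit-independent) within-group RSS.  Shape
    parameters are profiled on a coarse grid (closed-form weighted LS in e0
    and scale at each shape) and then polished by bounded least squares;
    ``polish=False`` keeps the grid solution (used for cheap bulk rewards).

    AIC = n log(RSS/n) + 2 (p + 1), p mean-structure parameters, +1 for the
    residual variance.
    """
    d = grid.array()
    n = summary.n.astype(float)
    ybar = summary.mean
    ntot = int(summary.n.sum())
    ed_lo, ed_hi = (_ED50_REL_BOUNDS[0] * grid.d_max, _ED50_REL_BOUNDS[1] * grid.d_max)

    if family == "linear":
        e0g, sg, rssg = _wls_profile(d[None, :], n, ybar)
        e0, scale, grp_rss, shape = float(e0g[0]), float(sg[0]), float(rssg[0]), ()
        converged = True
    elif family == "emax":
        ed_grid = np.geomspace(ed_lo, ed_hi, 30)
        F = d[None, :] / (ed_grid[:, None] + d[None, :])
        e0g, sg, rssg = _wls_profile(F, n, ybar)
        j = int(np.argmin(rssg))
        if polish:
            sw = np.sqrt(n)

            def resid(x):
                e0_, s_, led = x
                return sw * (ybar - e0_ - s_ * d / (np.exp(led) + d))

            sol = least_squares(
                resid, [e0g[j], sg[j], np.log(ed_grid[j])],
                bounds=([-np.inf, -np.inf, np.log(ed_lo)], [np.inf, np.inf, np.log(ed_hi)]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            e0, scale = float(sol.x[0]), float(sol.x[1])
            shape = (float(np.exp(sol.x[2])),)
            grp_rss = float(np.sum(sol.fun**2))
            converged = bool(sol.status > 0)
        else:
            e0, scale, grp_rss = float(e0g[j]), float(sg[j]), float(rssg[j])
            shape = (float(ed_grid[j]),)
            converged = True
    elif family == "sigemax":
        ed_grid = np.geomspace(max(ed_lo, 0.05), ed_hi, 24)
        h_grid = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
        EDg, Hg = (a.ravel() for a in np.meshgrid(ed_grid, h_grid, indexing="ij"))
        with np.errstate(divide="ignore", invalid="ignore"):
            dh = np.where(d[None, :] > 0, d[None, :] ** Hg[:, None], 0.0)
            F = dh / (EDg[:, None] ** Hg[:, None] + dh)
        e0g, sg, rssg = _wls_profile(F, n, ybar)
        j = int(np.argmin(rssg))
        if polish:
            sw = np.sqrt(n)

            def resid(x):
                e0_, s_, led, h_ = x
                ed = np.exp(led)
                with np.errstate(divide="ignore", invalid="ignore"):
                    fh = np.where(d > 0, d**h_, 0.0)
                    f = fh / (ed**h_ + fh)
                return sw * (ybar - e0_ - s_ * f)

            sol = least_squares(
                resid, [e0g[j], sg[j], np.log(EDg[j]), Hg[j]],
                bounds=([-np.inf, -np.inf, np.log(ed_lo), _HILL_BOUNDS[0]],
                        [np.inf, np.inf, np.log(ed_hi), _HILL_BOUNDS[1]]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            e0, scale = float(sol.x[0]), float(sol.x[1])
            shape = (float(np.exp(sol.x[2])), float(sol.x[3]))
            grp_rss = float(np.sum(sol.fun**2))
            converged = bool(sol.status > 0)
        else:
            e0, scale, grp_rss = float(e0g[j]), float(sg[j]), float(rssg[j])
            shape = (float(EDg[j]), float(Hg[j]))
            converged = True
    else:
        raise ValueError(f"no fitter for family {family!r}")

    rss = grp_rss + summary.rss_within
    p = _N_PARAMS[family]
    aic = ntot * np.log(max(rss, 1e-300) / ntot) + 2 * (p + 1)
    curve = DoseResponseCurve(family, e0=e0, scale=scale, shape=shape)
    return FitResult(family=family, e0=e0, scale=scale, shape=shape,
                     rss=rss, aic=aic, curve=curve, converged=converged)


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Minimum-AIC fit; ties broken by fewer parameters, then input order."""
    if not fits:
        raise ValueError("need at least one fit")
    return min(enumerate(fits), key=lambda t: (t[1].aic, t[1].n_params, t[0]))[1]


def estimate_target_dose(fit: FitResult, delta: float = DEFAULT_DELTA,
                         grid: DoseGrid = DEFAULT_GRID) -> Optional[float]:
    """Continuous MED read off the fitted curve (no rounding); None if the
    fitted effect never reaches delta in range."""
    return target_dose(fit.curve, delta, grid)


def compute_mae(fitted: DoseResponseCurve, truth: DoseResponseCurve,
                grid: DoseGrid = DEFAULT_GRID) -> float:
    """Mean absolute error between placebo-shifted curves over the active doses:
    mean over k >= 2 of |(muhat(d_k)-muhat(0)) - (mu(d_k)-mu(0))|."""
    d = grid.array()[1:]
    eff_hat = np.asarray(fitted(d)) - fitted(grid.doses[0])
    eff_true = np.asarray(truth(d)) - truth(grid.doses[0])
    return float(np.mean(np.abs(eff_hat - eff_true)))


@dataclass
class AnalysisResult:
    """Outcome of the end-of-trial MCP-Mod analysis."""

    significant: bool
    min_pvalue: float
    selected_family: str
    fitted_curve: DoseResponseCurve
    d_targ_hat: Optional[float]
    fits: Tuple[FitResult, ...] = ()
    test: Optional[TestResult] = None

    def mae_against(self, truth: DoseResponseCurve,
                    grid: DoseGrid = DEFAULT_GRID) -> float:
        return compute_mae(self.fitted_curve, truth, grid)

    def to_json(self) -> str:
        return json.dumps(dict(
            significant=bool(self.significant),
            min_pvalue=self.min_pvalue,
            selected_family=self.selected_family,
            e0=self.fitted_curve.e0,
            scale=self.fitted_curve.scale,
            shape=list(self.fitted_curve.shape),
            d_targ_hat=self.d_targ_hat,
        ))


def analyze_trial(summary: GroupSummary, candidates: CandidateSet,
                  alpha: float = 0.025, delta: float = DEFAULT_DELTA,
                  grid: DoseGrid = DEFAULT_GRID,
                  restrict_to_significant: bool = False,
                  polish: bool = True) -> AnalysisResult:
    """Full MCP-Mod chain: max-T test, candidate fits, AIC selection, MED.

    By default model selection formally uses all candidates regardless of the
    test outcome (the convention under which the performance metrics are
    evaluated); ``restrict_to_significant=True`` instead selects among the
    models whose adjusted p-value passes ``alpha``, when any does.
    """
    test = mct_test(summary, candidates, alpha=alpha, grid=grid,
                    per_model_pvalues=restrict_to_significant)
    fits = tuple(fit_candidate(summary, m.family, grid, polish=polish)
                 for m in candidates.models)
    pool = fits
    if restrict_to_significant and test.significant:
        keep = tuple(f for f, p in zip(fits, test.pvalues) if p <= alpha)
        if keep:
            pool = keep
    best = select_model(pool)
    return AnalysisResult(
        significant=test.significant, min_pvalue=test.min_pvalue,
        selected_family=best.family, fitted_curve=best.curve,
        d_targ_hat=estimate_target_dose(best, delta, grid),
        fits=fits, test=test,
    )
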