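"""Vectorized many-trials kernels used by RL training.

Everything here recomputes, across a whole batch of simulated trials at
once, what :mod:`adadose.mcpmod` computes for a single trial: grid-profiled
candidate fits, AIC selection, closed-form target doses, MAE, and max-T
significance.  The per-trial path is the reference; the batch path trades
the local least-squares polish for speed (the profile grids are identical,
so the two agree up to the polish refinement) and is cross-checked against
the reference in the test suite.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .dose_response import DoseGrid
from .mcpmod import CandidateSet, critical_value, optimal_contrasts

__all__ = ["shape_grid", "batch_fit_family", "batch_analyze", "SignificanceCache"]

_ED50_REL_BOUNDS = (0.001, 1.5)


def shape_grid(family: str, grid: DoseGrid) -> Tuple[np.ndarray, np.ndarray]:
    """(F, params) profile grid for a family: F is (G, K) standardized shapes,
    params is (G, n_shape).  Must stay in lockstep with the grids used by
    :func:`adadose.mcpmod.fit_candidate`."""
    d = grid.array()
    ed_lo, ed_hi = (_ED50_REL_BOUNDS[0] * grid.d_max, _ED50_REL_BOUNDS[1] * grid.d_max)
    if family == "linear":
        return d[None, :], np.zeros((1, 0))
    if family == "emax":
        ed = np.geomspace(ed_lo, ed_hi, 30)
        return d[None, :] / (ed[:, None] + d[None, :]), ed[:, None]
    if family == "sigemax":
        ed = np.geomspace(max(ed_lo, 0.05), ed_hi, 24)
        h = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
        EDg, Hg = (a.ravel() for a in np.meshgrid(ed, h, indexing="ij"))
        with np.errstate(divide="ignore", invalid="ignore"):
            dh = np.where(d[None, :] > 0, d[None, :] ** Hg[:, None], 0.0)
            F = dh / (EDg[:, None] ** Hg[:, None] + dh)
        return F, np.column_stack([EDg, Hg])
    raise ValueError(family)


def batch_fit_family(F: np.ndarray, n: np.ndarray, ybar: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-LS profile of a whole batch over a whole shape grid.

    F: (G, K) shapes; n, ybar: (E, K).  Returns per-(episode, grid-point)
    e0, scale, rss arrays of shape (E, G).
    """
    n = np.asarray(n, dtype=float)
    W = n.sum(axis=1)                       # (E,)
    Sf = n @ F.T                            # (E, G)
    Sff = n @ (F * F).T
    Sy = np.einsum("ek,ek->e", n, ybar)
    Syy = np.einsum("ek,ek->e", n, ybar**2)
    Sfy = (n * ybar) @ F.T                  # (E, G)
    det = W[:, None] * Sff - Sf**2
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(np.abs(det) > 1e-300,
                         (W[:, None] * Sfy - Sf * Sy[:, None]) / det, 0.0)
    e0 = (Sy[:, None] - scale * Sf) / W[:, None]
    rss = Syy[:, None] - e0 * Sy[:, None] - scale * Sfy
    return e0, scale, np.maximum(rss, 0.0)


def _closed_form_td(family: str, scale: np.ndarray, shape: np.ndarray,
                    delta: float, d_max: float) -> np.ndarray:
    """Target dose of a fitted monotone candidate, NaN where unreachable.

    linear: d = delta/scale; emax: d = delta*ed/(scale-delta);
    sigemax: d = ed * (delta/(scale-delta))^(1/h).  All require the fitted
    effect at d_max to reach delta.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "linear":
            td = delta / scale
        elif family == "emax":
            ed = shape[:, 0]
            td = delta * ed / (scale - delta)
        else:
            ed, h = shape[:, 0], shape[:, 1]
            td = ed * (delta / (scale - delta)) ** (1.0 / h)
        td = np.where((scale > 0) & np.isfinite(td) & (td >= 0) & (td <= d_max),
                      td, np.nan)
    return td


class SignificanceCache:
    """Max-T critical values memoized on the allocation-count vector.

    Training allocations are compositions of a few block sizes, so the same
    count vectors recur constantly; each distinct vector costs a handful of
    quasi-Monte-Carlo integrations once.
    """

    def __init__(self, candidates: CandidateSet, grid: DoseGrid, alpha: float):
        self.means = candidates.mean_matrix(grid)
        self.alpha = alpha
        self._cache: Dict[Tuple[int, ...], float] = {}

    def crit(self, n: np.ndarray) -> float:
        key = tuple(int(x) for x in n)
        if key not in self._cache:
            C = optimal_contrasts(self.means, n)
            df = int(n.sum() - len(n))
            self._cache[key] = critical_value(C, n, df, self.alpha)
        return self._cache[key]


def batch_analyze(n: np.ndarray, ybar: np.ndarray, rss_within: np.ndarray,
                  candidates: CandidateSet, grid: DoseGrid, delta: float,
                  sig_cache: Optional[SignificanceCache] = None) -> dict:
    """Batch MCP-Mod Mod-step (grid-profile fits) and optional MCP-step.

    Returns per-episode arrays: ``selected`` (candidate index), ``effects``
    (fitted placebo-shifted effects at the active doses), ``td_hat`` (NaN
    when undefined) and, when ``sig_cache`` is given, ``significant``.
    """
    E = n.shape[0]
    ntot = n.sum(axis=1)
    fams = candidates.families
    aics, tds, effects = [], [], []
    d_act = grid.array()[1:]
    for fam in fams:
        F, params = shape_grid(fam, grid)
        e0, scale, rss_grp = batch_fit_family(F, n, ybar)
        j = np.argmin(rss_grp, axis=1)
        rows = np.arange(E)
        e0b, scaleb, rssb = e0[rows, j], scale[rows, j], rss_grp[rows, j]
        shapeb = params[j]
        p = {"linear": 2, "emax": 3, "sigemax": 4}[fam]
        rss_tot = rssb + rss_within
        aics.append(ntot * np.log(np.maximum(rss_tot, 1e-300) / ntot) + 2 * (p + 1))
        tds.append(_closed_form_td(fam, scaleb, shapeb, delta, grid.d_max))
        if fam == "linear":
            Fb = np.repeat(d_act[None, :], E, axis=0)
        elif fam == "emax":
            ed = shapeb[:, 0]
            Fb = d_act[None, :] / (ed[:, None] + d_act[None, :])
        else:
            ed, h = shapeb[:, 0], shapeb[:, 1]
            Fb = d_act[None, :] ** h[:, None] / (ed[:, None] ** h[:, None]
                                                 + d_act[None, :] ** h[:, None])
        effects.append(scaleb[:, None] * Fb)

    aic_mat = np.stack(aics)                      # (M, E)
    # argmin takes the first minimum: candidate order (linear, emax, sigemax)
    # is also increasing parameter count, matching the AIC tie-break
    selected = np.argmin(aic_mat, axis=0)
    eff_sel = np.stack(effects)[selected, np.arange(E)]
    td_sel = np.stack(tds)[selected, np.arange(E)]

    out = dict(selected=selected, effects=eff_sel, td_hat=td_sel, aic=aic_mat)
    if sig_cache is not None:
        sigma2 = rss_within / (ntot - n.shape[1])
        sig = np.empty(E, dtype=bool)
        for e in range(E):
            C = optimal_contrasts(sig_cache.means, n[e])
            v = ((C**2) / n[e][:, None]).sum(axis=0)
            t = (C.T @ ybar[e]) / np.sqrt(sigma2[e] * v)
            sig[e] = t.max() > sig_cache.crit(n[e])
        out["significant"] = sig
    return out
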