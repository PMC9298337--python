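"""Dose-response curve families, calibration, and target-dose geometry.

The simulation world is a five-arm phase II trial on the dose grid
(0, 2, 4, 6, 8) mg with a continuous efficacy endpoint.  True mean responses
come from one of six parametric families (linear, Emax, sigmoid Emax,
quadratic, exponential, flat), each written as

    mu(d) = e0 + scale * f(d; shape)

where ``f`` is a standardized shape function with ``f(0) = 0``.  Curves are
*calibrated*: ``scale`` is chosen so that the maximum of ``mu(d) - mu(0)``
over the dose range equals a prescribed maximum effect (attained at the top
dose for the monotone families, at the interior vertex for the quadratic).

The target dose (minimum effective dose) for a clinically relevant effect
``delta`` is the smallest dose whose effect over placebo reaches ``delta``,
solved as a continuous quantity.  The target-dose interval for a relative
band ``eta`` brackets the doses whose effect is within ``delta * (1 ± eta)``;
an absent or out-of-range upper end is clipped to the top dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "FAMILIES",
    "DoseGrid",
    "DoseResponseCurve",
    "Scenario",
    "DEFAULT_DELTA",
    "DEFAULT_ETA",
    "calibrate_curve",
    "evaluate_curve",
    "target_dose",
    "target_dose_interval",
    "build_scenario_table",
    "scenario_frame",
]

FAMILIES = ("linear", "emax", "sigemax", "quadratic", "exponential", "flat")

#: clinically relevant effect over placebo (response units)
DEFAULT_DELTA = 1.3
#: relative half-width of the target-effect band
DEFAULT_ETA = 0.1


@dataclass(frozen=True)
class DoseGrid:
    """Ordered dose amounts in mg; the first entry is placebo (0)."""

    doses: Tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.size < 2:
            raise ValueError("need at least two doses")
        if d[0] != 0.0:
            raise ValueError("first dose must be placebo (0)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.doses)

    @property
    def d_max(self) -> float:
        return self.doses[-1]

    def array(self) -> np.ndarray:
        return np.asarray(self.doses, dtype=float)


DEFAULT_GRID = DoseGrid()


def _shape_function(family: str, d: np.ndarray, shape: Tuple[float, ...]) -> np.ndarray:
    """Standardized shape f(d) with f(0) = 0."""
    d = np.asarray(d, dtype=float)
    if family == "linear":
        return d
    if family == "emax":
        (ed50,) = shape
        return d / (ed50 + d)
    if family == "sigemax":
        ed50, h = shape
        with np.errstate(divide="ignore", invalid="ignore"):
            dh = np.where(d > 0, d**h, 0.0)
        return dh / (ed50**h + dh)
    if family == "quadratic":
        (vertex,) = shape
        return d * (2.0 * vertex - d) / vertex**2
    if family == "exponential":
        (rate,) = shape
        return np.expm1(d / rate)
    if family == "flat":
        return np.zeros_like(d)
    raise ValueError(f"unknown dose-response family: {family!r}")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Parametric mean response mu(d) = e0 + scale * f(d; shape).

    ``shape`` holds the family-specific shape parameters:
    emax ``(ed50,)``, sigemax ``(ed50, hill)``, quadratic ``(vertex,)``,
    exponential ``(rate,)``; empty for linear and flat.
    """

    family: str
    e0: float = 0.0
    scale: float = 1.0
    shape: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown dose-response family: {self.family!r}")

    def __call__(self, d) -> np.ndarray | float:
        out = self.e0 + self.scale * _shape_function(self.family, d, self.shape)
        if np.isscalar(d):
            return float(out)
        return out

    @property
    def monotone(self) -> bool:
        return self.family not in ("quadratic", "flat")


def evaluate_curve(curve: DoseResponseCurve, d) -> np.ndarray | float:
    """Mean response mu(d); thin functional alias for ``curve(d)``."""
    return curve(d)


def calibrate_curve(
    family: str,
    shape: Sequence[float],
    max_effect: float,
    grid: DoseGrid = DEFAULT_GRID,
    e0: float = 0.0,
) -> DoseResponseCurve:
    """Build a curve whose maximum effect over the dose range is ``max_effect``.

    For monotone families the maximum of mu(d) - mu(0) sits at the top dose;
    for the quadratic it sits at the interior vertex.  ``scale`` is solved
    exactly from the standardized shape; full precision is kept (the 2-3
    significant digits usually printed for such coefficients are not enough
    to reproduce target doses to 0.01 mg).
    """
    shape = tuple(float(s) for s in shape)
    if max_effect < 0:
        raise ValueError("max_effect must be nonnegative")
    if family == "flat":
        if max_effect != 0:
            raise ValueError("flat family cannot attain a nonzero max effect")
        return DoseResponseCurve("flat", e0=e0, scale=0.0, shape=())
    if family == "emax" and shape[0] <= 0:
        raise ValueError("ED50 must be positive")
    if family == "sigemax" and (shape[0] <= 0 or shape[1] <= 0):
        raise ValueError("ED50 and Hill exponent must be positive")
    if family == "quadratic":
        d_peak = min(shape[0], grid.d_max)
    else:
        d_peak = grid.d_max
    f_peak = float(_shape_function(family, np.asarray(d_peak), shape))
    return DoseResponseCurve(family, e0=e0, scale=max_effect / f_peak, shape=shape)


def _first_crossing(curve: DoseResponseCurve, level: float, grid: DoseGrid,
                    n_scan: int = 512, xtol: float = 1e-9) -> Optional[float]:
    """Smallest d in [0, d_max] with mu(d) - mu(0) >= level, or None.

    Coarse scan to bracket the first upcrossing, then Brent refinement.
    Works for non-monotone (e.g. quadratic) curves as well.
    """
    if level <= 0:
        return 0.0
    d = np.linspace(0.0, grid.d_max, n_scan + 1)
    g = np.asarray(curve(d)) - curve(0.0) - level
    above = np.nonzero(g >= 0)[0]
    if above.size == 0:
        return None
    j = above[0]
    if j == 0:
        return 0.0
    return float(brentq(lambda x: curve(x) - curve(0.0) - level,
                        d[j - 1], d[j], xtol=xtol))


def target_dose(curve: DoseResponseCurve, delta: float = DEFAULT_DELTA,
                grid: DoseGrid = DEFAULT_GRID) -> Optional[float]:
    """Continuous minimum effective dose for effect ``delta``, or None.

    Solves arg min_{d in [0, d_max]} { mu(d) >= mu(0) + delta } to ~1e-9 mg.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    return _first_crossing(curve, delta, grid)


def target_dose_interval(curve: DoseResponseCurve, delta: float = DEFAULT_DELTA,
                         eta: float = DEFAULT_ETA, grid: DoseGrid = DEFAULT_GRID
                         ) -> Optional[Tuple[float, float]]:
    """Dose interval whose effects lie within delta*(1 ± eta).

    The upper end is clipped to the top dose when the larger effect is never
    reached in range; the interval is undefined when even the lower effect
    delta*(1-eta) is unreachable.
    """
    if not 0 < eta < 1:
        raise ValueError("eta must be in (0, 1)")
    lower = _first_crossing(curve, delta * (1.0 - eta), grid)
    if lower is None:
        return None
    upper = _first_crossing(curve, delta * (1.0 + eta), grid)
    if upper is None:
        upper = grid.d_max
    return (lower, min(upper, grid.d_max))


@dataclass(frozen=True)
class Scenario:
    """One true dose-response world used in the simulation study."""

    id: int
    curve: DoseResponseCurve
    max_effect: float
    d_targ: Optional[float] = None
    interval: Optional[Tuple[float, float]] = None

    @property
    def family(self) -> str:
        return self.curve.family

    @property
    def is_flat(self) -> bool:
        return self.curve.family == "flat"


# (family, shape parameters) for the five non-flat blocks of the scenario
# table; each block appears at max effects 1.65, 1.65*0.8, 1.65*1.2.
_SCENARIO_BLOCKS = (
    ("linear", ()),
    ("emax", (0.79,)),
    ("sigemax", (4.0, 5.0)),
    ("quadratic", (6.0,)),
    ("exponential", (1.0,)),
)
_BASE_MAX_EFFECT = 1.65
_EFFECT_MULTIPLIERS = (1.0, 0.8, 1.2)


def build_scenario_table(grid: DoseGrid = DEFAULT_GRID,
                         delta: float = DEFAULT_DELTA,
                         eta: float = DEFAULT_ETA) -> list[Scenario]:
    """The 16 true scenarios: 5 families x 3 effect sizes, plus flat.

    Scenarios 1/4/7 (linear, Emax ED50=0.79, sigEmax ED50=4 h=5 at max effect
    1.65) double as the MCP-Mod candidate set.  The off-candidate effect
    sizes (x0.8, x1.2) and families (quadratic, exponential) probe
    robustness; scenario 16 (flat) measures the type I error rate.
    """
    scenarios: list[Scenario] = []
    sid = 1
    for family, shape in _SCENARIO_BLOCKS:
        for mult in _EFFECT_MULTIPLIERS:
            me = _BASE_MAX_EFFECT * mult
            curve = calibrate_curve(family, shape, me, grid)
            scenarios.append(Scenario(
                id=sid, curve=curve, max_effect=me,
                d_targ=target_dose(curve, delta, grid),
                interval=target_dose_interval(curve, delta, eta, grid),
            ))
            sid += 1
    flat = calibrate_curve("flat", (), 0.0, grid)
    scenarios.append(Scenario(id=sid, curve=flat, max_effect=0.0))
    return scenarios


def scenario_frame(scenarios: Sequence[Scenario]) -> pd.DataFrame:
    """Tabular export of a scenario list (CSV-ready)."""
    rows = []
    for s in scenarios:
        lo, up = s.interval if s.interval is not None else (np.nan, np.nan)
        rows.append(dict(id=s.id, family=s.family, max_effect=s.max_effect,
                         d_targ=np.nan if s.d_targ is None else s.d_targ,
                         lower=lo, upper=up))
    return pd.DataFrame(rows)
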