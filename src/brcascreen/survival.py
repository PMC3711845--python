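"""Stage-specific survival and competing mortality.

Cancer survival after diagnosis is modelled with two-parameter Weibull
curves calibrated exactly to a pair of interval-survival anchors (5- and
10-year survival by stage at diagnosis).  Patients who survive ten years
after diagnosis are considered cured and face background mortality only.
Deaths occurring more than 18 months (three cycles) after diagnosis are
preceded by three cycles of progressive disease.

Competing (non-breast-cancer) mortality follows a Gompertz hazard
``a * exp(b * age)``; the slope ``b`` is fixed and the level ``a`` is
calibrated so the full screening model reproduces a target all-cause
mortality by a given age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np


class CalibrationError(ValueError):
    """Raised when survival or mortality calibration is infeasible."""


@dataclass(frozen=True)
class WeibullSpec:
    """Weibull survival curve S(t) = exp(-(t/scale)**shape), t in years.

    A degenerate spec (``degenerate=True``) represents a stage with no
    excess mortality (in-situ disease): S(t) = 1 for all t.
    """

    shape: float
    scale: float
    stage: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and (self.shape <= 0 or self.scale <= 0):
            raise CalibrationError(
                f"Weibull parameters must be positive (stage={self.stage!r}, "
                f"shape={self.shape}, scale={self.scale})"
            )

    def survival(self, t):
        """Survival probability at time t (years since diagnosis)."""
        t = np.asarray(t, dtype=float)
        if self.degenerate:
            return np.ones_like(t)
        return np.exp(-np.power(np.maximum(t, 0.0) / self.scale, self.shape))


def fit_weibull_two_points(
    s1: float, s2: float, t1: float, t2: float, stage: str = ""
) -> WeibullSpec:
    """Calibrate a Weibull exactly through two survival anchors.

    Closed form: ``k = ln(ln s2 / ln s1) / ln(t2 / t1)`` and
    ``lambda = t1 / (-ln s1)**(1/k)``.  The returned curve reproduces
    (s1, t1) and (s2, t2) to machine precision.
    """
    if not (0.0 < t1 < t2):
        raise CalibrationError(f"need 0 < t1 < t2, got ({t1}, {t2})")
    if not (0.0 < s2 < s1 < 1.0):
        raise CalibrationError(
            f"need 0 < s2 < s1 < 1 for a two-point Weibull fit, got "
            f"s1={s1}, s2={s2} (stage={stage!r}); use a degenerate spec for "
            "stages with no excess mortality"
        )
    shape = math.log(math.log(s2) / math.log(s1)) / math.log(t2 / t1)
    scale = t1 / (-math.log(s1)) ** (1.0 / shape)
    return WeibullSpec(shape=shape, scale=scale, stage=stage)


def death_density_by_cycle(
    w: WeibullSpec, n_cycles: int, cycle_len: float
) -> np.ndarray:
    """Unconditional cancer-death probability per cycle since diagnosis.

    Entry ``j`` (1-based) is ``S((j-1)*h) - S(j*h)``.  With the ten-year
    cure rule only the first ``n_cycles`` entries are used; survivors at
    that point stop dying of cancer.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    edges = np.arange(n_cycles + 1) * cycle_len
    s = w.survival(edges)
    return s[:-1] - s[1:]


@dataclass(frozen=True)
class TerminalPathway:
    """Progressive-disease occupancy preceding a cancer death."""

    death_cycle: int
    progressive_cycles: tuple[int, ...]


def terminal_pathway_allocation(death_cycle: int) -> TerminalPathway:
    """Allocate the progressive-disease cycles preceding a cancer death.

    Deaths within three cycles of diagnosis go straight to dead; later
    deaths spend the three cycles immediately before death in progressive
    disease (end-of-life costs and the progression utility override the
    treatment/remission assignment for those cycles).
    """
    if death_cycle < 1:
        raise ValueError("death_cycle must be >= 1")
    if death_cycle <= 3:
        return TerminalPathway(death_cycle, ())
    return TerminalPathway(
        death_cycle, tuple(range(death_cycle - 3, death_cycle))
    )


@dataclass(frozen=True)
class BackgroundMortality:
    """Gompertz competing mortality: hazard ``a * exp(b * age)`` per year."""

    a: float
    b: float
    target: tuple[float, float] | None = None  # (cum. mortality, by age)

    def cycle_probs(self, ages: np.ndarray, cycle_len: float) -> np.ndarray:
        """Per-cycle death probability for cycles starting at ``ages``."""
        ages = np.asarray(ages, dtype=float)
        cum_haz = (self.a / self.b) * (
            np.exp(self.b * (ages + cycle_len)) - np.exp(self.b * ages)
        )
        return 1.0 - np.exp(-cum_haz)


def calibrate_background_mortality(
    target: tuple[float, float],
    disease_params,
    *,
    b: float = 0.09,
    bracket: tuple[float, float] = (1e-8, 5e-3),
    tol: float = 1e-6,
    max_iter: int = 200,
) -> BackgroundMortality:
    """Solve the Gompertz level ``a`` by bisection.

    ``target`` is (cumulative all-cause mortality, by age) for the
    mammography-alone arm of the full model at the supplied parameters.
    """
    from .engine import run_cohort  # deferred: engine depends on this module

    p_target, by_age = target
    if not (0.0 < p_target < 1.0):
        raise CalibrationError(
            f"target cumulative mortality must be in (0,1), got {p_target}"
        )

    def mortality_at(a: float) -> float:
        bg = BackgroundMortality(a=a, b=b, target=target)
        trial = replace(disease_params, background=bg)
        trace = run_cohort("mammography_only", trial)
        return 1.0 - trace.survival_to_age(by_age)

    lo, hi = bracket
    f_lo = mortality_at(lo) - p_target
    f_hi = mortality_at(hi) - p_target
    if f_lo > 0:
        raise CalibrationError(
            f"target all-cause mortality {p_target:.3f} by age {by_age} is "
            f"below the cancer-only mortality of the model "
            f"({p_target + f_lo:.3f}); no non-negative background hazard "
            "can reach it"
        )
    if f_hi < 0:
        raise CalibrationError(
            f"bisection bracket {bracket} does not reach target {p_target}"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # hazard level spans orders of magnitude
        f_mid = mortality_at(mid) - p_target
        if abs(f_mid) < tol:
            return BackgroundMortality(a=mid, b=b, target=target)
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    return BackgroundMortality(a=math.sqrt(lo * hi), b=b, target=target)
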