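"""Model inputs and calibration of their sampling distributions.

Every input of the screening model — age-specific incidence, screen
sensitivity/specificity, stage-at-diagnosis distributions, unit costs,
health-state utilities and interval-survival anchors — is published as a
mean with a 95% confidence interval.  This module turns those printed
summaries into concrete parameter values (:class:`ParameterSet`) and into
sampling distributions for probabilistic sensitivity analysis
(:class:`ParameterSpec`):

* probabilities and utilities -> Beta, calibrated by matching the printed
  mean exactly and the CI endpoints in least squares over the
  concentration;
* costs -> Gamma, same scheme over the shape;
* stage rows -> Dirichlet, with the effective sample size chosen to match
  the widest printed per-component CI;
* structural constants (ages, cycle length, discount rate) -> fixed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .survival import BackgroundMortality, WeibullSpec, fit_weibull_two_points

STAGES = ("in_situ", "local", "regional", "distant")
MODES = ("mri_detected", "mam_detected", "non_screen")

DAYS_PER_YEAR = 365.25


class CalibrationError(ValueError):
    """A printed (mean, CI) triple cannot be represented as requested."""


class ValidationError(ValueError):
    """A configuration document violates a model-input invariant."""


# --------------------------------------------------------------------------
# Distribution specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain model input with its sampling distribution.

    ``params``: (alpha, beta) for Beta; (shape, scale) for Gamma;
    concentration vector for Dirichlet; (value,) for fixed.
    ``source`` records the printed (mean, ci_lo, ci_hi).
    """

    family: str
    params: tuple[float, ...]
    source: tuple[float, float, float] | None = None
    fit_error: float = 0.0
    note: str = ""

    def mean(self):
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            k, theta = self.params
            return k * theta
        if self.family == "dirichlet":
            alpha = np.asarray(self.params)
            return alpha / alpha.sum()
        if self.family == "fixed":
            return self.params[0]
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator):
        if self.family == "beta":
            return rng.beta(*self.params)
        if self.family == "gamma":
            k, theta = self.params
            return rng.gamma(k) * theta
        if self.family == "dirichlet":
            return rng.dirichlet(self.params)
        if self.family == "fixed":
            return self.params[0]
        raise ValueError(f"unknown family {self.family!r}")

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        if self.family == "beta":
            return tuple(stats.beta.ppf([lo_q, hi_q], *self.params))
        if self.family == "gamma":
            k, theta = self.params
            return tuple(stats.gamma.ppf([lo_q, hi_q], k, scale=theta))
        if self.family == "fixed":
            return (self.params[0], self.params[0])
        raise ValueError(f"no scalar interval for family {self.family!r}")


def fixed(value: float) -> DistributionSpec:
    return DistributionSpec("fixed", (float(value),))


def _coverage_note(spec: DistributionSpec) -> str:
    """Check the 10%-relative-coverage contract against the printed CI."""
    if spec.source is None or spec.family == "fixed":
        return ""
    mean, lo, hi = spec.source
    q_lo, q_hi = spec.interval()
    msgs = []
    for name, printed, fitted in (("lower", lo, q_lo), ("upper", hi, q_hi)):
        scale = abs(printed) if printed != 0 else max(abs(hi - lo), 1e-12)
        if abs(fitted - printed) > 0.10 * scale:
            msgs.append(
                f"{name} CI endpoint fitted {fitted:.4g} vs printed "
                f"{printed:.4g}"
            )
    return "; ".join(msgs)


def beta_from_mean_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Beta with the printed mean held exactly, CI matched in least squares.

    A one-dimensional search over the concentration ``nu = alpha + beta``
    minimizes the squared error of the 2.5%/97.5% quantiles against the
    printed interval.  If the coverage contract cannot be met a warning is
    recorded in the returned spec's ``note``; the fit is still returned.
    """
    if not (0.0 < mean < 1.0):
        raise CalibrationError(f"Beta mean must be in (0,1), got {mean}")
    if not (0.0 <= lo < mean < hi <= 1.0):
        raise CalibrationError(
            f"need 0 <= lo < mean < hi <= 1, got ({mean}, {lo}, {hi})"
        )

    def loss(log_nu: float) -> float:
        nu = math.exp(log_nu)
        q = stats.beta.ppf([0.025, 0.975], mean * nu, (1 - mean) * nu)
        return (q[0] - lo) ** 2 + (q[1] - hi) ** 2

    res = optimize.minimize_scalar(
        loss, bounds=(math.log(2.0), math.log(1e7)), method="bounded",
        options={"xatol": 1e-7},
    )
    nu = math.exp(res.x)
    spec = DistributionSpec(
        "beta", (mean * nu, (1 - mean) * nu), (mean, lo, hi),
        fit_error=math.sqrt(res.fun),
    )
    return replace(spec, note=_coverage_note(spec))


def gamma_from_mean_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Gamma with mean ``shape * scale`` held exactly; CI least-squares fit."""
    if not (0.0 < lo < mean < hi):
        raise CalibrationError(
            f"need 0 < lo < mean < hi, got ({mean}, {lo}, {hi})"
        )

    def loss(log_k: float) -> float:
        k = math.exp(log_k)
        q = stats.gamma.ppf([0.025, 0.975], k, scale=mean / k)
        return (q[0] - lo) ** 2 + (q[1] - hi) ** 2

    res = optimize.minimize_scalar(
        loss, bounds=(math.log(0.02), math.log(1e6)), method="bounded",
        options={"xatol": 1e-7},
    )
    k = math.exp(res.x)
    spec = DistributionSpec(
        "gamma", (k, mean / k), (mean, lo, hi), fit_error=math.sqrt(res.fun)
    )
    return replace(spec, note=_coverage_note(spec))


# --------------------------------------------------------------------------
# Stage distributions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageDistribution:
    """Dirichlet-distributed stage-at-diagnosis row for one detection mode."""

    mode: str
    p: tuple[float, float, float, float]
    ess: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"stage probabilities must be a simplex vector, got {self.p}"
            )
        if self.ess <= 0:
            raise ValidationError("effective sample size must be positive")

    @property
    def alphas(self) -> np.ndarray:
        return self.ess * np.asarray(self.p)

    def mean(self) -> np.ndarray:
        return np.asarray(self.p)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        if not math.isfinite(self.ess):  # point mass: no sampling uncertainty
            return np.asarray(self.p)
        return rng.dirichlet(self.alphas)


def dirichlet_from_stage_row(
    p: Sequence[float],
    ess: float | None = None,
    ci: Mapping[str, Sequence[float]] | None = None,
    mode: str = "",
) -> StageDistribution:
    """Build the Dirichlet for a printed stage row.

    Rows summing to within 2% of 1 (rounding artifacts) are renormalized
    proportionally; a larger discrepancy is a configuration error.  When
    ``ess`` is not given it is fitted so the Beta marginal of the component
    with the widest printed CI matches that CI in least squares.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or np.any(p < 0):
        raise ValidationError(f"stage row must be 4 non-negative values: {p}")
    total = p.sum()
    if not (0.98 <= total <= 1.02):
        raise ValidationError(
            f"stage row {mode!r} sums to {total:.3f}, outside [0.98, 1.02]"
        )
    p_norm = p / total

    if ess is None:
        if ci is None:
            raise ValidationError(
                "either ess or per-component CIs are required to build a "
                "stage Dirichlet"
            )
        widths = {s: ci[s][1] - ci[s][0] for s in STAGES}
        target_stage = max(widths, key=widths.get)
        idx = STAGES.index(target_stage)
        m = p_norm[idx]
        lo, hi = ci[target_stage]

        def loss(log_ess: float) -> float:
            e = math.exp(log_ess)
            q = stats.beta.ppf([0.025, 0.975], e * m, e * (1 - m))
            return (q[0] - lo) ** 2 + (q[1] - hi) ** 2

        res = optimize.minimize_scalar(
            loss, bounds=(math.log(2.0), math.log(1e5)), method="bounded",
            options={"xatol": 1e-7},
        )
        ess = math.exp(res.x)

    return StageDistribution(mode=mode, p=tuple(p_norm), ess=float(ess))


# --------------------------------------------------------------------------
# Screening performance
# --------------------------------------------------------------------------

def derive_conditional_sensitivities(
    se_a: float, se_b: float, se_either: float
) -> tuple[float, float]:
    """Sensitivity of each modality after a false negative by the other.

    From the marginal sensitivities and the sensitivity of detection by
    either modality, the joint-detection probability is
    ``joint = se_a + se_b - se_either``; the conditionals follow as
    ``(se_a - joint) / (1 - se_b)`` and ``(se_b - joint) / (1 - se_a)``.
    A modality with perfect sensitivity leaves no false negatives, so the
    corresponding conditional is 0 by convention.
    """
    for name, v in (("se_a", se_a), ("se_b", se_b)):
        if not (0.0 <= v <= 1.0):
            raise CalibrationError(f"{name}={v} outside [0,1]")
    if not (max(se_a, se_b) - 1e-12 <= se_either <= min(1.0, se_a + se_b) + 1e-12):
        raise CalibrationError(
            f"inconsistent sensitivity triple (se_a={se_a}, se_b={se_b}, "
            f"se_either={se_either}): need max(se_a, se_b) <= se_either "
            "<= min(1, se_a + se_b)"
        )
    joint = se_a + se_b - se_either
    if not (max(0.0, se_a + se_b - 1.0) - 1e-12 <= joint
            <= min(se_a, se_b) + 1e-12):
        raise CalibrationError(
            f"implied joint detection probability {joint:.4f} infeasible for "
            f"(se_a={se_a}, se_b={se_b}, se_either={se_either})"
        )
    a_given_b_neg = 0.0 if se_b >= 1.0 else (se_a - joint) / (1.0 - se_b)
    b_given_a_neg = 0.0 if se_a >= 1.0 else (se_b - joint) / (1.0 - se_a)
    return (min(max(a_given_b_neg, 0.0), 1.0),
            min(max(b_given_a_neg, 0.0), 1.0))


@dataclass(frozen=True)
class MamAloneBand:
    age_lo: float
    age_hi: float
    se: float
    sp: float


@dataclass(frozen=True)
class ScreenPerformance:
    """Sensitivity/specificity of the screening tests.

    ``se_mam_in_combined``/``sp_mam_in_combined`` are the fixed
    meta-analytic mammography values used while the programme alternates
    MRI and mammography; ``mam_alone_by_age`` holds the age-specific values
    used for mammography-alone screening (and for mammography offered past
    the MRI age range).  The last age band extends upward to cover
    screening beyond its printed upper limit.
    """

    se_combined: float
    sp_combined: float
    se_mri: float
    sp_mri: float
    se_mam_in_combined: float
    sp_mam_in_combined: float
    se_mri_given_mam_fn: float
    se_mam_given_mri_fn: float
    mam_alone_by_age: tuple[MamAloneBand, ...]

    def __post_init__(self) -> None:
        vals = (
            self.se_combined, self.sp_combined, self.se_mri, self.sp_mri,
            self.se_mam_in_combined, self.sp_mam_in_combined,
            self.se_mri_given_mam_fn, self.se_mam_given_mri_fn,
        )
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValidationError("screen performance values must be in [0,1]")
        if self.se_combined + 1e-12 < max(self.se_mri, self.se_mam_in_combined):
            raise ValidationError(
                "combined sensitivity cannot be below either marginal"
            )

    @classmethod
    def from_marginals(
        cls,
        se_combined: float,
        sp_combined: float,
        se_mri: float,
        sp_mri: float,
        se_mam: float,
        sp_mam: float,
        mam_alone_by_age: Iterable[MamAloneBand],
    ) -> "ScreenPerformance":
        se_mri_c, se_mam_c = derive_conditional_sensitivities(
            se_mri, se_mam, se_combined
        )
        return cls(
            se_combined=se_combined, sp_combined=sp_combined,
            se_mri=se_mri, sp_mri=sp_mri,
            se_mam_in_combined=se_mam, sp_mam_in_combined=sp_mam,
            se_mri_given_mam_fn=se_mri_c, se_mam_given_mri_fn=se_mam_c,
            mam_alone_by_age=tuple(mam_alone_by_age),
        )

    def mam_alone_band(self, age: float) -> MamAloneBand:
        bands = self.mam_alone_by_age
        for band in bands:
            if band.age_lo <= age < band.age_hi:
                return band
        if age >= bands[-1].age_hi:
            return bands[-1]
        return bands[0]


# --------------------------------------------------------------------------
# Incidence
# --------------------------------------------------------------------------

def band_risk_to_cycle_prob(risk10: float, cycles_per_band: int) -> float:
    """Constant-hazard conversion of a band risk to a per-cycle probability.

    Compounding the result over ``cycles_per_band`` cycles recovers the
    band risk exactly: ``1 - (1 - p_c)**n = risk``.
    """
    if not (0.0 <= risk10 < 1.0):
        raise ValidationError(
            f"band risk must be in [0,1), got {risk10} (risk of 1 implies an "
            "infinite hazard)"
        )
    if cycles_per_band < 1:
        raise ValidationError("cycles_per_band must be >= 1")
    return 1.0 - (1.0 - risk10) ** (1.0 / cycles_per_band)


@dataclass(frozen=True)
class IncidenceSchedule:
    """Age-banded 10-year risks of first breast cancer onset."""

    bands: tuple[tuple[float, float, float], ...]  # (age_lo, age_hi, risk10)

    def __post_init__(self) -> None:
        bands = self.bands
        if not bands:
            raise ValidationError("incidence schedule is empty")
        for lo, hi, r in bands:
            if not (0.0 <= r < 1.0):
                raise ValidationError(f"band risk {r} outside [0,1)")
            if hi <= lo:
                raise ValidationError(f"band ({lo},{hi}) is empty")
        for (l0, h0, _), (l1, h1, _) in zip(bands, bands[1:]):
            if not math.isclose(h0, l1):
                raise ValidationError(
                    f"incidence bands must be contiguous; gap between {h0} "
                    f"and {l1}"
                )

    def cycle_prob(self, age: float, cycle_len: float) -> float:
        """Per-cycle onset probability at ``age``.

        Ages above the last band reuse its hazard; ages below the first
        band carry zero risk.
        """
        bands = self.bands
        if age < bands[0][0]:
            return 0.0
        band = bands[-1]
        for b in bands:
            if b[0] <= age < b[1]:
                band = b
                break
        lo, hi, r = band
        n = int(round((hi - lo) / cycle_len))
        return band_risk_to_cycle_prob(r, n)


# --------------------------------------------------------------------------
# Costs, utilities, model configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CostSet:
    """Unit costs (2008 CAD).

    Treatment totals cover the first 18 months after diagnosis and are
    allocated in equal thirds over the three treatment cycles; likewise
    the end-of-life total over the three terminal cycles.
    """

    c_mri: float
    c_mam: float
    c_workup: float
    treat_total: Mapping[str, float]
    eol_total: float

    def __post_init__(self) -> None:
        vals = [self.c_mri, self.c_mam, self.c_workup, self.eol_total,
                *self.treat_total.values()]
        if any(v < 0 for v in vals):
            raise ValidationError("costs must be non-negative")
        if set(self.treat_total) != set(STAGES):
            raise ValidationError(
                f"treatment costs must cover stages {STAGES}"
            )

    def c_treat(self, stage: str) -> tuple[float, float, float]:
        per = self.treat_total[stage] / 3.0
        return (per, per, per)

    @property
    def c_eol(self) -> tuple[float, float, float]:
        per = self.eol_total / 3.0
        return (per, per, per)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights.

    The diagnostic work-up utility applies for a two-week excursion within
    the 6-month cycle; its QALY decrement per work-up is
    ``(1 - u_workup) * workup_duration / 365.25``.
    """

    u_workup: float
    u_treat: Mapping[str, float]
    u_progression: float
    u_remission: float
    u_well: float = 1.0
    u_dead: float = 0.0
    workup_duration_days: float = 14.0

    def __post_init__(self) -> None:
        vals = [self.u_workup, self.u_progression, self.u_remission,
                self.u_well, self.u_dead, *self.u_treat.values()]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValidationError("utilities must be in [0,1]")
        if self.u_dead != 0.0 or self.u_well != 1.0:
            raise ValidationError("u_dead must be 0 and u_well must be 1")
        if set(self.u_treat) != set(STAGES):
            raise ValidationError(f"utilities must cover stages {STAGES}")

    @property
    def workup_decrement(self) -> float:
        return (1.0 - self.u_workup) * self.workup_duration_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class ModelConfig:
    start_age: float = 25.0
    horizon_age: float = 100.0
    cycle_len: float = 0.5
    discount_rate: float = 0.035
    mri_ages: tuple[float, float] = (25.0, 64.0)
    mam_ages: tuple[float, float] = (30.0, 79.0)
    treatment_cycles: int = 3
    cure_cycles: int = 20
    terminal_cycles: int = 3
    wtp_grid: tuple[float, ...] = (0.0, 50000.0, 100000.0)

    def __post_init__(self) -> None:
        if self.cycle_len <= 0:
            raise ValidationError("cycle length must be positive")
        if self.discount_rate < 0:
            raise ValidationError("discount rate must be non-negative")
        if self.terminal_cycles != 3 or self.treatment_cycles != 3:
            raise ValidationError(
                "the terminal pathway and treatment window are both three "
                "cycles long in this model"
            )
        if self.horizon_age <= self.start_age:
            raise ValidationError("horizon must exceed the start age")
        if self.cure_cycles * self.cycle_len != 10.0:
            raise ValidationError("the cure rule is ten years after diagnosis")

    @property
    def n_cycles(self) -> int:
        return int(round((self.horizon_age - self.start_age) / self.cycle_len))

    def ages(self) -> np.ndarray:
        """Age at the start of each cycle."""
        return self.start_age + self.cycle_len * np.arange(self.n_cycles)


# --------------------------------------------------------------------------
# Aggregates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """One complete, concrete instantiation of every model input."""

    incidence: IncidenceSchedule
    screen: ScreenPerformance
    stage_dists: Mapping[str, StageDistribution]
    costs: CostSet
    utilities: UtilitySet
    survival: Mapping[str, WeibullSpec]
    background: BackgroundMortality
    config: ModelConfig

    def __post_init__(self) -> None:
        if set(self.stage_dists) != set(MODES):
            raise ValidationError(f"stage distributions must cover {MODES}")
        if set(self.survival) != set(STAGES):
            raise ValidationError(f"survival specs must cover {STAGES}")


@dataclass(frozen=True)
class ParameterSpec:
    """The uncertain counterpart of :class:`ParameterSet`.

    Each numeric leaf carries a :class:`DistributionSpec`; structural
    pieces (age bands, model configuration) are shared.
    """

    incidence_bands: tuple[tuple[float, float, DistributionSpec], ...]
    screen: Mapping[str, DistributionSpec]        # se/sp leaves
    mam_alone: tuple[tuple[float, float, DistributionSpec, DistributionSpec], ...]
    stage_rows: Mapping[str, StageDistribution]
    costs: Mapping[str, DistributionSpec]
    utilities: Mapping[str, DistributionSpec]
    survival_anchors: Mapping[str, tuple[DistributionSpec, DistributionSpec] | None]
    anchor_times: tuple[float, float]
    background: BackgroundMortality
    config: ModelConfig
    raw_config: Mapping = field(default_factory=dict, compare=False)

    def fingerprint(self) -> str:
        """Stable hash of the underlying configuration document."""
        text = json.dumps(self.raw_config, sort_keys=True, default=float)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    # -- deterministic extraction -----------------------------------------
    def mean_parameter_set(self) -> ParameterSet:
        """The all-means ParameterSet (the deterministic base case)."""
        incidence = IncidenceSchedule(tuple(
            (lo, hi, ds.mean()) for lo, hi, ds in self.incidence_bands
        ))
        screen = ScreenPerformance.from_marginals(
            se_combined=self.screen["se_combined"].mean(),
            sp_combined=self.screen["sp_combined"].mean(),
            se_mri=self.screen["se_mri"].mean(),
            sp_mri=self.screen["sp_mri"].mean(),
            se_mam=self.screen["se_mam"].mean(),
            sp_mam=self.screen["sp_mam"].mean(),
            mam_alone_by_age=[
                MamAloneBand(lo, hi, se.mean(), sp.mean())
                for lo, hi, se, sp in self.mam_alone
            ],
        )
        stage_dists = dict(self.stage_rows)
        costs = CostSet(
            c_mri=self.costs["mri_screen"].mean(),
            c_mam=self.costs["mammogram"].mean(),
            c_workup=self.costs["workup"].mean(),
            treat_total={s: self.costs[f"treat_{s}"].mean() for s in STAGES},
            eol_total=self.costs["end_of_life"].mean(),
        )
        utilities = UtilitySet(
            u_workup=self.utilities["workup"].mean(),
            u_treat={s: self.utilities[f"treat_{s}"].mean() for s in STAGES},
            u_progression=self.utilities["progression"].mean(),
            u_remission=self.utilities["remission"].mean(),
            workup_duration_days=self.utilities["workup_duration_days"].mean(),
        )
        t1, t2 = self.anchor_times
        surv: dict[str, WeibullSpec] = {}
        for stage in STAGES:
            anchors = self.survival_anchors[stage]
            if anchors is None:
                surv[stage] = WeibullSpec(1.0, 1.0, stage=stage, degenerate=True)
            else:
                surv[stage] = fit_weibull_two_points(
                    anchors[0].mean(), anchors[1].mean(), t1, t2, stage=stage
                )
        return ParameterSet(
            incidence=incidence, screen=screen, stage_dists=stage_dists,
            costs=costs, utilities=utilities, survival=surv,
            background=self.background, config=self.config,
        )

    def validation_report(self) -> dict[str, dict]:
        """Goodness-of-fit of every calibrated distribution, keyed by path."""
        report: dict[str, dict] = {}

        def add(path: str, ds: DistributionSpec) -> None:
            report[path] = {
                "family": ds.family,
                "mean": float(np.asarray(ds.mean()).ravel()[0])
                if ds.family != "dirichlet" else list(map(float, ds.mean())),
                "fit_error": ds.fit_error,
                "status": "warn" if ds.note else "ok",
                "note": ds.note,
            }

        for lo, hi, ds in self.incidence_bands:
            add(f"incidence.{int(lo)}-{int(hi)}", ds)
        for key, ds in self.screen.items():
            add(f"screening.combined.{key}", ds)
        for lo, hi, se, sp in self.mam_alone:
            add(f"screening.mammography_alone.{int(lo)}-{int(hi)}.se", se)
            add(f"screening.mammography_alone.{int(lo)}-{int(hi)}.sp", sp)
        for mode, row in self.stage_rows.items():
            report[f"stages.{mode}"] = {
                "family": "dirichlet", "mean": list(map(float, row.p)),
                "ess": row.ess, "status": "ok", "note": "",
            }
        for key, ds in self.costs.items():
            add(f"costs.{key}", ds)
        for key, ds in self.utilities.items():
            add(f"utilities.{key}", ds)
        for stage, anchors in self.survival_anchors.items():
            if anchors is None:
                continue
            add(f"survival.{stage}.s5", anchors[0])
            add(f"survival.{stage}.s10", anchors[1])
        return report


# --------------------------------------------------------------------------
# Configuration loading
# --------------------------------------------------------------------------

def _require(section: Mapping, key: str, path: str):
    if key not in section:
        raise ValidationError(f"missing key {path}.{key}")
    return section[key]


def _mean_ci(node: Mapping, path: str) -> tuple[float, float, float]:
    mean = _require(node, "mean", path)
    ci = _require(node, "ci", path)
    if len(ci) != 2 or not ci[0] <= mean <= ci[1]:
        raise ValidationError(
            f"{path}: CI {ci} must bracket the mean {mean}"
        )
    return float(mean), float(ci[0]), float(ci[1])


def _beta_leaf(node: Mapping, path: str) -> DistributionSpec:
    try:
        return beta_from_mean_ci(*_mean_ci(node, path))
    except CalibrationError as err:
        raise ValidationError(f"{path}: {err}") from err


def _gamma_leaf(node: Mapping, path: str) -> DistributionSpec:
    try:
        return gamma_from_mean_ci(*_mean_ci(node, path))
    except CalibrationError as err:
        raise ValidationError(f"{path}: {err}") from err


def load_parameter_spec(config_text: str) -> ParameterSpec:
    """Parse and validate a configuration document into a ParameterSpec.

    Raises :class:`ValidationError` naming the offending path on any
    missing key or invariant failure.
    """
    cfg = yaml.safe_load(config_text)
    if not isinstance(cfg, Mapping):
        raise ValidationError("configuration document must be a mapping")
    for section in ("model", "incidence", "screening", "stages", "costs",
                    "utilities", "survival", "background_mortality"):
        _require(cfg, section, "<root>")

    m = cfg["model"]
    config = ModelConfig(
        start_age=float(_require(m, "start_age", "model")),
        horizon_age=float(_require(m, "horizon_age", "model")),
        cycle_len=float(_require(m, "cycle_length_years", "model")),
        discount_rate=float(_require(m, "discount_rate", "model")),
        mri_ages=tuple(_require(m, "mri_ages", "model")),
        mam_ages=tuple(_require(m, "mam_ages", "model")),
        treatment_cycles=int(m.get("treatment_cycles", 3)),
        cure_cycles=int(m.get("cure_cycles", 20)),
        terminal_cycles=int(m.get("terminal_cycles", 3)),
        wtp_grid=tuple(cfg.get("psa", {}).get("wtp_grid", (0.0, 50000.0,
                                                           100000.0))),
    )

    bg_cfg = cfg["background_mortality"]
    target = (
        float(_require(bg_cfg, "target_cum_mortality", "background_mortality")),
        float(_require(bg_cfg, "target_age", "background_mortality")),
    )
    a = bg_cfg.get("gompertz_a")
    background = BackgroundMortality(
        a=float(a) if a is not None else float("nan"),
        b=float(_require(bg_cfg, "gompertz_b", "background_mortality")),
        target=target,
    )

    bands = []
    for i, band in enumerate(cfg["incidence"]):
        path = f"incidence[{i}]"
        lo, hi = _require(band, "ages", path)
        mean = float(_require(band, "risk10", path))
        ci = _require(band, "ci", path)
        bands.append((float(lo), float(hi),
                      _beta_leaf({"mean": mean, "ci": ci}, path)))
    # structural check via the schedule type (contiguity, range)
    IncidenceSchedule(tuple((lo, hi, ds.mean()) for lo, hi, ds in bands))

    sc = _require(cfg["screening"], "combined", "screening")
    screen = {
        "se_combined": _beta_leaf(_require(sc, "se_both", "screening.combined"),
                                  "screening.combined.se_both"),
        "sp_combined": _beta_leaf(_require(sc, "sp_both", "screening.combined"),
                                  "screening.combined.sp_both"),
        "se_mri": _beta_leaf(_require(sc, "se_mri", "screening.combined"),
                             "screening.combined.se_mri"),
        "sp_mri": _beta_leaf(_require(sc, "sp_mri", "screening.combined"),
                             "screening.combined.sp_mri"),
        "se_mam": _beta_leaf(_require(sc, "se_mam", "screening.combined"),
                             "screening.combined.se_mam"),
        "sp_mam": _beta_leaf(_require(sc, "sp_mam", "screening.combined"),
                             "screening.combined.sp_mam"),
    }
    # fail fast if the mean triple cannot yield conditional sensitivities
    derive_conditional_sensitivities(
        screen["se_mri"].mean(), screen["se_mam"].mean(),
        screen["se_combined"].mean(),
    )

    mam_alone = []
    for i, band in enumerate(_require(cfg["screening"], "mammography_alone",
                                      "screening")):
        path = f"screening.mammography_alone[{i}]"
        lo, hi = _require(band, "ages", path)
        mam_alone.append((
            float(lo), float(hi),
            _beta_leaf(_require(band, "se", path), f"{path}.se"),
            _beta_leaf(_require(band, "sp", path), f"{path}.sp"),
        ))

    stage_rows = {}
    for mode in MODES:
        node = _require(cfg["stages"], mode, "stages")
        try:
            stage_rows[mode] = dirichlet_from_stage_row(
                _require(node, "p", f"stages.{mode}"),
                ess=node.get("ess"),
                ci=node.get("ci"),
                mode=mode,
            )
        except ValidationError as err:
            raise ValidationError(f"stages.{mode}: {err}") from err

    cc = cfg["costs"]
    costs = {
        "mri_screen": _gamma_leaf(_require(cc, "mri_screen", "costs"),
                                  "costs.mri_screen"),
        "mammogram": _gamma_leaf(_require(cc, "mammogram", "costs"),
                                 "costs.mammogram"),
        "workup": _gamma_leaf(_require(cc, "workup", "costs"), "costs.workup"),
        "end_of_life": _gamma_leaf(_require(cc, "end_of_life", "costs"),
                                   "costs.end_of_life"),
    }
    treat = _require(cc, "treatment", "costs")
    for stage in STAGES:
        costs[f"treat_{stage}"] = _gamma_leaf(
            _require(treat, stage, "costs.treatment"),
            f"costs.treatment.{stage}",
        )

    uc = cfg["utilities"]
    utilities = {
        "workup": _beta_leaf(_require(uc, "workup", "utilities"),
                             "utilities.workup"),
        "progression": _beta_leaf(_require(uc, "progression", "utilities"),
                                  "utilities.progression"),
        "remission": _beta_leaf(_require(uc, "remission", "utilities"),
                                "utilities.remission"),
        "workup_duration_days": fixed(uc.get("workup_duration_days", 14)),
    }
    ut = _require(uc, "treatment", "utilities")
    for stage in STAGES:
        utilities[f"treat_{stage}"] = _beta_leaf(
            _require(ut, stage, "utilities.treatment"),
            f"utilities.treatment.{stage}",
        )

    sv = cfg["survival"]
    anchors: dict[str, tuple[DistributionSpec, DistributionSpec] | None] = {}
    for stage in STAGES:
        node = _require(sv, stage, "survival")
        if node is None:
            anchors[stage] = None
            continue
        s5 = _beta_leaf(_require(node, "s5", f"survival.{stage}"),
                        f"survival.{stage}.s5")
        s10 = _beta_leaf(_require(node, "s10", f"survival.{stage}"),
                         f"survival.{stage}.s10")
        if not s10.mean() < s5.mean():
            raise ValidationError(
                f"survival.{stage}: 10-year survival must be below 5-year"
            )
        anchors[stage] = (s5, s10)

    return ParameterSpec(
        incidence_bands=tuple(bands),
        screen=screen,
        mam_alone=tuple(mam_alone),
        stage_rows=stage_rows,
        costs=costs,
        utilities=utilities,
        survival_anchors=anchors,
        anchor_times=(5.0, 10.0),
        background=background,
        config=config,
        raw_config=cfg,
    )


def default_config_text() -> str:
    """The packaged default configuration document."""
    return (resources.files("brcascreen") / "data" / "default_config.yaml"
            ).read_text()


def load_default_spec() -> ParameterSpec:
    return load_parameter_spec(default_config_text())
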