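"""Parameter uncertainty: probabilistic and deterministic sensitivity analysis.

The probabilistic sensitivity analysis (PSA) propagates the calibrated
input distributions through the paired cohort model with a single master
random generator and a documented draw order (incidence bands, screen
performance, age-specific mammography, stage rows, costs, utilities,
survival anchors), so results are bit-reproducible given (spec
fingerprint, seed, n).  Decision uncertainty is summarized on the
cost-effectiveness plane and as a cost-effectiveness acceptability curve
(CEAC) under the net-monetary-benefit rule; ties count as cost-effective.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import engine
from .parameters import (
    STAGES,
    CostSet,
    IncidenceSchedule,
    MamAloneBand,
    ParameterSet,
    ParameterSpec,
    ScreenPerformance,
    StageDistribution,
    UtilitySet,
    ValidationError,
    derive_conditional_sensitivities,
    dirichlet_from_stage_row,
)
from .survival import WeibullSpec, fit_weibull_two_points


class SamplingError(RuntimeError):
    """A parameter leaf persistently violated its invariants when sampled."""


_MAX_RETRIES = 1000


def _draw_screen_triple(spec: ParameterSpec, rng: np.random.Generator):
    """Sample (se_mri, se_mam, se_combined) until the triple is coherent."""
    for _ in range(_MAX_RETRIES):
        se_mri = spec.screen["se_mri"].sample(rng)
        se_mam = spec.screen["se_mam"].sample(rng)
        se_comb = spec.screen["se_combined"].sample(rng)
        if max(se_mri, se_mam) <= se_comb <= min(1.0, se_mri + se_mam):
            return se_mri, se_mam, se_comb
    raise SamplingError(
        "screen sensitivity triple (se_mri, se_mam, se_combined) failed the "
        "joint-detection feasibility condition after repeated resampling"
    )


def _draw_anchor_pair(anchors, rng: np.random.Generator, stage: str):
    for _ in range(_MAX_RETRIES):
        s5 = anchors[0].sample(rng)
        s10 = anchors[1].sample(rng)
        if 0.0 < s10 < s5 < 1.0:
            return s5, s10
    raise SamplingError(
        f"survival anchors for stage {stage!r} failed s10 < s5 after "
        "repeated resampling"
    )


def sample_parameter_set(spec: ParameterSpec,
                         rng: np.random.Generator) -> ParameterSet:
    """Draw one coherent ParameterSet from the calibrated distributions.

    Conditional screen sensitivities are re-derived from the sampled
    marginals each draw, so the joint-detection identity holds exactly;
    leaves whose draws violate an invariant are resampled (bounded).
    """
    incidence = IncidenceSchedule(tuple(
        (lo, hi, ds.sample(rng)) for lo, hi, ds in spec.incidence_bands
    ))

    se_mri, se_mam, se_comb = _draw_screen_triple(spec, rng)
    sp_mri = spec.screen["sp_mri"].sample(rng)
    sp_mam = spec.screen["sp_mam"].sample(rng)
    sp_comb = spec.screen["sp_combined"].sample(rng)
    mam_alone = [
        MamAloneBand(lo, hi, se.sample(rng), sp.sample(rng))
        for lo, hi, se, sp in spec.mam_alone
    ]
    screen = ScreenPerformance.from_marginals(
        se_combined=se_comb, sp_combined=sp_comb, se_mri=se_mri,
        sp_mri=sp_mri, se_mam=se_mam, sp_mam=sp_mam,
        mam_alone_by_age=mam_alone,
    )

    stage_dists = {
        mode: StageDistribution(mode=mode,
                                p=tuple(row.sample(rng)), ess=row.ess)
        for mode, row in spec.stage_rows.items()
    }

    costs = CostSet(
        c_mri=spec.costs["mri_screen"].sample(rng),
        c_mam=spec.costs["mammogram"].sample(rng),
        c_workup=spec.costs["workup"].sample(rng),
        treat_total={s: spec.costs[f"treat_{s}"].sample(rng) for s in STAGES},
        eol_total=spec.costs["end_of_life"].sample(rng),
    )
    utilities = UtilitySet(
        u_workup=spec.utilities["workup"].sample(rng),
        u_treat={s: spec.utilities[f"treat_{s}"].sample(rng) for s in STAGES},
        u_progression=spec.utilities["progression"].sample(rng),
        u_remission=spec.utilities["remission"].sample(rng),
        workup_duration_days=spec.utilities["workup_duration_days"].mean(),
    )

    t1, t2 = spec.anchor_times
    survival: dict[str, WeibullSpec] = {}
    for stage in STAGES:
        anchors = spec.survival_anchors[stage]
        if anchors is None:
            survival[stage] = WeibullSpec(1.0, 1.0, stage=stage,
                                          degenerate=True)
        else:
            s5, s10 = _draw_anchor_pair(anchors, rng, stage)
            survival[stage] = fit_weibull_two_points(s5, s10, t1, t2,
                                                     stage=stage)

    return ParameterSet(
        incidence=incidence, screen=screen, stage_dists=stage_dists,
        costs=costs, utilities=utilities, survival=survival,
        background=spec.background, config=spec.config,
    )


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-draw incremental outcomes with provenance."""

    draws: pd.DataFrame
    n_draws: int
    seed: int
    spec_fingerprint: str

    def summary(self) -> dict:
        df = self.draws
        ci = lambda col: tuple(np.percentile(df[col], [2.5, 97.5]))
        mean_d_cost = float(df["d_cost"].mean())
        mean_d_qaly = float(df["d_qaly"].mean())
        per_draw_icer = df["d_cost"] / df["d_qaly"]
        valid = df["d_qaly"] > 0
        out = {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "mean": {c: float(df[c].mean()) for c in df.columns},
            "ci95": {c: ci(c) for c in df.columns},
            "incremental_cost": mean_d_cost,
            "incremental_qaly": mean_d_qaly,
            "icer_ratio_of_means": engine.icer_or_label(mean_d_cost,
                                                        mean_d_qaly),
            "frac_less_effective": float((df["d_qaly"] < 0).mean()),
            "frac_dominated_draws": float((~valid & (df["d_cost"] >= 0)
                                           ).mean()),
            "icer_percentiles_positive_d_qaly": tuple(
                np.percentile(per_draw_icer[valid], [2.5, 50, 97.5])
            ) if valid.any() else None,
        }
        return out


def run_psa(spec: ParameterSpec, n_draws: int, seed: int) -> PSAResult:
    """Monte Carlo over the input distributions, both arms per draw.

    Each draw evaluates the combined and mammography-alone strategies on
    the *same* ParameterSet.  Draws that fail an engine precondition are
    resampled; more than 1% failures aborts the analysis.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    failures = 0
    while len(records) < n_draws:
        try:
            params = sample_parameter_set(spec, rng)
            res = engine.evaluate_strategies(params)
        except (SamplingError, ValidationError):
            failures += 1
            if failures > max(10, 0.01 * n_draws):
                raise SamplingError(
                    "more than 1% of PSA draws failed engine preconditions"
                )
            continue
        comb, mam = res["combined"], res["mammography_only"]
        rec = {
            "cost_combined": comb["cost"],
            "qaly_combined": comb["qaly"],
            "cost_mammography": mam["cost"],
            "qaly_mammography": mam["qaly"],
            "d_cost": comb["cost"] - mam["cost"],
            "d_qaly": comb["qaly"] - mam["qaly"],
            "incidence_by_65": mam["incidence_by_65"],
            "prog_sens_combined": comb["program_sensitivity"],
            "prog_sens_mammography": mam["program_sensitivity"],
            "survival_combined": comb["survival_to_65"],
            "survival_mammography": mam["survival_to_65"],
        }
        for i, s in enumerate(STAGES):
            rec[f"stage_{s}_combined"] = comb["stage_distribution"][i]
            rec[f"stage_{s}_mammography"] = mam["stage_distribution"][i]
        records.append(rec)
    return PSAResult(draws=pd.DataFrame.from_records(records),
                     n_draws=n_draws, seed=seed,
                     spec_fingerprint=spec.fingerprint())


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_cost_effective: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_cost_effective <= 1.0):
            raise ValueError("probability must be in [0,1]")


def compute_ceac(psa: PSAResult,
                 wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Acceptability curve under the net-monetary-benefit rule.

    At each willingness-to-pay lambda, the probability that the combined
    strategy is cost-effective is the fraction of draws with
    ``lambda * dQALY - dCost >= 0`` (ties count as cost-effective; at
    lambda 0 this is the fraction of cost-saving draws).
    """
    if len(wtp_grid) == 0:
        raise ValueError("willingness-to-pay grid is empty")
    d_cost = psa.draws["d_cost"].to_numpy()
    d_qaly = psa.draws["d_qaly"].to_numpy()
    return [
        CEACPoint(float(w),
                  float(np.mean(w * d_qaly - d_cost >= 0.0)))
        for w in wtp_grid
    ]


# --------------------------------------------------------------------------
# Deterministic sensitivity analysis
# --------------------------------------------------------------------------

def _rebuild_screen(screen: ScreenPerformance, **updates) -> ScreenPerformance:
    vals = {
        "se_combined": screen.se_combined, "sp_combined": screen.sp_combined,
        "se_mri": screen.se_mri, "sp_mri": screen.sp_mri,
        "se_mam": screen.se_mam_in_combined,
        "sp_mam": screen.sp_mam_in_combined,
    }
    vals.update(updates)
    return ScreenPerformance.from_marginals(
        mam_alone_by_age=screen.mam_alone_by_age, **vals
    )


def _param_setters() -> Mapping[str, callable]:
    setters: dict[str, callable] = {
        "costs.c_mri": lambda p, v: replace(
            p, costs=replace(p.costs, c_mri=v)),
        "costs.c_mam": lambda p, v: replace(
            p, costs=replace(p.costs, c_mam=v)),
        "costs.c_workup": lambda p, v: replace(
            p, costs=replace(p.costs, c_workup=v)),
        "costs.eol_total": lambda p, v: replace(
            p, costs=replace(p.costs, eol_total=v)),
        "screen.se_mri": lambda p, v: replace(
            p, screen=_rebuild_screen(p.screen, se_mri=v)),
        "screen.sp_mri": lambda p, v: replace(
            p, screen=_rebuild_screen(p.screen, sp_mri=v)),
        "screen.se_mam": lambda p, v: replace(
            p, screen=_rebuild_screen(p.screen, se_mam=v)),
        "screen.sp_mam": lambda p, v: replace(
            p, screen=_rebuild_screen(p.screen, sp_mam=v)),
        "screen.se_combined": lambda p, v: replace(
            p, screen=_rebuild_screen(p.screen, se_combined=v)),
        "utilities.u_workup": lambda p, v: replace(
            p, utilities=replace(p.utilities, u_workup=v)),
        "utilities.u_progression": lambda p, v: replace(
            p, utilities=replace(p.utilities, u_progression=v)),
        "utilities.u_remission": lambda p, v: replace(
            p, utilities=replace(p.utilities, u_remission=v)),
        "model.discount_rate": lambda p, v: replace(
            p, config=replace(p.config, discount_rate=v)),
        "model.horizon_age": lambda p, v: replace(
            p, config=replace(p.config, horizon_age=v)),
        "background.a": lambda p, v: replace(
            p, background=replace(p.background, a=v)),
    }
    for stage in STAGES:
        setters[f"costs.treat_total.{stage}"] = (
            lambda p, v, s=stage: replace(
                p, costs=replace(
                    p.costs,
                    treat_total={**dict(p.costs.treat_total), s: v}))
        )
        setters[f"utilities.u_treat.{stage}"] = (
            lambda p, v, s=stage: replace(
                p, utilities=replace(
                    p.utilities,
                    u_treat={**dict(p.utilities.u_treat), s: v}))
        )
    for mode in ("mri_detected", "mam_detected", "non_screen"):
        setters[f"stages.{mode}"] = (
            lambda p, v, m=mode: replace(
                p, stage_dists={
                    **dict(p.stage_dists),
                    m: dirichlet_from_stage_row(
                        v, ess=p.stage_dists[m].ess, mode=m),
                })
        )
    return setters


def set_param(params: ParameterSet, path: str, value) -> ParameterSet:
    """Return a copy of ``params`` with one leaf replaced.

    Replacing a marginal screen sensitivity re-derives the conditional
    sensitivities so the joint-detection identity keeps holding.
    """
    setters = _param_setters()
    if path not in setters:
        raise ValueError(
            f"unknown parameter path {path!r}; valid paths: "
            + ", ".join(sorted(setters))
        )
    return setters[path](params, value)


def one_way_sensitivity(
    spec: ParameterSpec, param_path: str, values: Sequence[float]
) -> list[tuple[float, float | str]]:
    """ICER at the mean ParameterSet with one leaf varied over ``values``."""
    base = spec.mean_parameter_set()
    out = []
    for v in values:
        params = set_param(base, param_path, v)
        res = engine.evaluate_strategies(params)
        d_cost = res["combined"]["cost"] - res["mammography_only"]["cost"]
        d_qaly = res["combined"]["qaly"] - res["mammography_only"]["qaly"]
        out.append((v, engine.icer_or_label(d_cost, d_qaly)))
    return out


@dataclass
class TornadoEntry:
    parameter: str
    low_value: object
    high_value: object
    icer_low: float | str
    icer_high: float | str
    width: float


def _stage_row_extremes(spec: ParameterSpec, mode: str):
    """One-way range for a stage row: the in-situ share moved to its CI
    endpoints, the invasive shares rescaled proportionally.

    Moving every component to a CI extreme simultaneously would leave the
    joint 95% region by a wide margin, so the row is varied along a single
    interpretable direction (share of in-situ disease).
    """
    try:
        ci = spec.raw_config["stages"][mode]["ci"]["in_situ"]
    except (KeyError, TypeError):
        return None
    p = np.asarray(spec.stage_rows[mode].p)
    rows = []
    for target in ci:
        row = p.copy()
        row[1:] *= (1.0 - target) / (1.0 - p[0])
        row[0] = target
        rows.append(tuple(row))
    return tuple(rows)


def default_tornado_ranges(spec: ParameterSpec) -> dict[str, tuple]:
    """Default one-way ranges.

    The MRI unit price uses the programme's published one-way range
    ($200-$700 per scan); screen performance uses the printed 95% CIs;
    the discount rate spans 0-5%/yr; the MRI-detected stage row moves its
    in-situ share across its CI.
    """
    ranges: dict[str, tuple] = {}
    ranges["costs.c_mri"] = (200.0, 700.0)
    for leaf, path in (("se_mri", "screen.se_mri"),
                       ("sp_mri", "screen.sp_mri")):
        s = spec.screen[leaf].source
        ranges[path] = (s[1], s[2])
    ranges["model.discount_rate"] = (0.0, 0.05)
    extremes = _stage_row_extremes(spec, "mri_detected")
    if extremes is not None:
        ranges["stages.mri_detected"] = extremes
    return ranges


def tornado(spec: ParameterSpec,
            param_ranges: Mapping[str, tuple] | None = None
            ) -> list[TornadoEntry]:
    """One-way ICER swings, sorted for a tornado diagram (widest first)."""
    if param_ranges is None:
        param_ranges = default_tornado_ranges(spec)
    base = spec.mean_parameter_set()
    entries = []
    for path, (lo, hi) in param_ranges.items():
        icers = []
        for v in (lo, hi):
            params = set_param(base, path, v)
            res = engine.evaluate_strategies(params)
            d_cost = res["combined"]["cost"] - res["mammography_only"]["cost"]
            d_qaly = res["combined"]["qaly"] - res["mammography_only"]["qaly"]
            icers.append(engine.icer_or_label(d_cost, d_qaly))
        finite = [x for x in icers if isinstance(x, float)]
        width = (abs(icers[1] - icers[0]) if len(finite) == 2
                 else float("inf"))
        entries.append(TornadoEntry(path, lo, hi, icers[0], icers[1], width))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries
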