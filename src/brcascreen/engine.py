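"""Deterministic expected-value cohort engine.

One strategy arm (alternating MRI/mammography, or annual mammography
alone) is evaluated as a Markov cohort model with 6-month cycles from age
25 to the horizon.  Pre-diagnosis dynamics (onset, screening, detection,
false positives) are propagated in closed form; post-diagnosis pathways
(treatment, remission, progressive disease, cure, cancer death) are
expanded into per-cycle accrual streams by stage and folded over the
diagnosis-incidence vector by discrete convolution, so a full arm
evaluation costs a handful of vector operations.

Conventions (documented in the methods note):

* no half-cycle correction — state membership is evaluated at cycle end,
  and per-cycle utility accrues to those alive at cycle end;
* screening, work-up costs and the two-week work-up disutility accrue at
  the screen regardless of death later in the same cycle;
* discounting multiplies by ``(1+r)**(-t)`` with ``t`` the years from
  cohort entry to the end of the accruing cycle;
* cancer death and background death compete independently; cancer death
  takes bookkeeping precedence within a cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (
    MODES,
    STAGES,
    ParameterSet,
    ScreenPerformance,
    CostSet,
    UtilitySet,
    ModelConfig,
    ValidationError,
)
from .survival import death_density_by_cycle, terminal_pathway_allocation

ARMS = ("combined", "mammography_only")

EVENT_NONE, EVENT_MRI, EVENT_MAM = 0, 1, 2
_EVENT_NAMES = {EVENT_NONE: "none", EVENT_MRI: "mri", EVENT_MAM: "mammogram"}


# --------------------------------------------------------------------------
# Screening schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningSchedule:
    arm: str
    events: tuple[int, ...]  # per-cycle event codes
    config: ModelConfig

    def event_name(self, cycle: int) -> str:
        return _EVENT_NAMES[self.events[cycle]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.events, dtype=np.int8)


@lru_cache(maxsize=32)
def build_screening_schedule(arm: str, config: ModelConfig) -> ScreeningSchedule:
    """Deterministic per-cycle event list for one strategy arm.

    Combined arm: MRI annually at whole ages within the MRI age range,
    mammography annually at half ages within the mammography age range —
    so the two alternate every six months where both are offered, MRI
    stands alone below the mammography start age and mammography stands
    alone above the MRI stop age.  Mammography-alone arm: one mammogram
    annually at whole ages within the mammography age range.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    ages = config.ages()
    frac = ages - np.floor(ages)
    at_whole = np.isclose(frac, 0.0)
    at_half = np.isclose(frac, 0.5)
    events = np.full(config.n_cycles, EVENT_NONE, dtype=np.int8)
    mri_lo, mri_hi = config.mri_ages
    mam_lo, mam_hi = config.mam_ages
    if arm == "combined":
        events[at_whole & (ages >= mri_lo) & (ages <= mri_hi)] = EVENT_MRI
        mam_year = np.floor(ages)
        events[at_half & (mam_year >= mam_lo) & (mam_year <= mam_hi)] = EVENT_MAM
    else:
        events[at_whole & (ages >= mam_lo) & (ages <= mam_hi)] = EVENT_MAM
    return ScreeningSchedule(arm=arm, events=tuple(int(e) for e in events),
                             config=config)


# --------------------------------------------------------------------------
# Detection and false-positive logic
# --------------------------------------------------------------------------

def detection_probability(
    event: str,
    prior_event: str | None,
    age: float,
    perf: ScreenPerformance,
    arm: str = "combined",
    mri_age_hi: float = 64.0,
) -> float:
    """Probability a prevalent undetected cancer is found at this screen.

    The first screen after onset uses the modality's marginal sensitivity;
    a screen immediately following a false negative by the *opposite*
    modality uses the conditional sensitivity (a repeat of the same
    modality, which the standard schedules never produce, falls back to
    the marginal).  In the mammography-alone arm — and for mammography
    offered above the MRI age range in the combined arm — the age-specific
    sensitivities apply.
    """
    if event == "none":
        return 0.0
    if arm == "mammography_only":
        return perf.mam_alone_band(age).se
    if event == "mri":
        if prior_event == "mammogram":
            return perf.se_mri_given_mam_fn
        return perf.se_mri
    if event == "mammogram":
        if prior_event == "mri":
            return perf.se_mam_given_mri_fn
        if age > mri_age_hi + 0.5:
            return perf.mam_alone_band(age).se
        return perf.se_mam_in_combined
    raise ValueError(f"unknown event {event!r}")


def _specificity(event: int, age: float, perf: ScreenPerformance,
                 arm: str, mri_age_hi: float) -> float:
    if event == EVENT_NONE:
        return 1.0
    if arm == "mammography_only":
        return perf.mam_alone_band(age).sp
    if event == EVENT_MRI:
        return perf.sp_mri
    if age > mri_age_hi + 0.5:
        return perf.mam_alone_band(age).sp
    return perf.sp_mam_in_combined


def false_positive_flow(
    event: str,
    perf: ScreenPerformance,
    costs: CostSet,
    utils: UtilitySet,
) -> tuple[float, float]:
    """Expected work-up cost and QALY decrement per cancer-free screenee.

    A fraction ``1 - specificity`` of cancer-free attendees receive a
    diagnostic work-up (cost ``c_workup``) and lose
    ``(1 - u_workup) * 14/365.25`` QALYs for the two-week excursion; they
    return to the well state within the same cycle.
    """
    if event == "none":
        return (0.0, 0.0)
    sp = perf.sp_mri if event == "mri" else perf.sp_mam_in_combined
    fp = 1.0 - sp
    return (fp * costs.c_workup, fp * utils.workup_decrement)


# --------------------------------------------------------------------------
# Post-diagnosis accrual streams
# --------------------------------------------------------------------------

@dataclass
class _StageStreams:
    """Per-cycle-since-diagnosis expectation streams for one stage.

    All streams are conditional on no background death; index 0 holds
    cycle 1 after diagnosis.  ``alive`` is the probability of not having
    died of cancer by the end of the cycle; ``util`` is QALYs per cycle
    (utility x cycle length); occupancy streams split ``alive`` into the
    treatment / remission / progressive / cured states.
    """

    cost: np.ndarray
    util: np.ndarray
    alive: np.ndarray
    occ_treat: np.ndarray
    occ_rem: np.ndarray
    occ_prog: np.ndarray
    occ_cured: np.ndarray
    dead_ca_inc: np.ndarray


def _build_stage_streams(stage: str, params: ParameterSet) -> _StageStreams:
    cfg = params.config
    T = cfg.n_cycles
    h = cfg.cycle_len
    n_cure = cfg.cure_cycles
    d = death_density_by_cycle(params.survival[stage], n_cure, h)
    w_surv = 1.0 - d.sum()

    u = params.utilities
    c_treat = params.costs.treat_total[stage] / cfg.treatment_cycles
    c_eol = params.costs.eol_total / cfg.terminal_cycles
    u_treat, u_rem, u_prog = u.u_treat[stage], u.u_remission, u.u_progression

    cost = np.zeros(T)
    util = np.zeros(T)
    occ_treat = np.zeros(T)
    occ_rem = np.zeros(T)
    occ_prog = np.zeros(T)
    occ_cured = np.zeros(T)
    dead_inc = np.zeros(T)

    # death paths: cancer death in cycle k after diagnosis
    for k in range(1, n_cure + 1):
        wk = d[k - 1]
        if wk <= 0.0:
            continue
        dead_inc[k - 1] += wk
        prog = set(terminal_pathway_allocation(k).progressive_cycles)
        for i in range(1, k):  # alive cycles; nothing accrues in cycle k
            if i in prog:
                cost[i - 1] += wk * c_eol
                util[i - 1] += wk * u_prog * h
                occ_prog[i - 1] += wk
            elif i <= cfg.treatment_cycles:
                cost[i - 1] += wk * c_treat
                util[i - 1] += wk * u_treat * h
                occ_treat[i - 1] += wk
            else:
                util[i - 1] += wk * u_rem * h
                occ_rem[i - 1] += wk

    # survivor path: treatment, remission, then cured at ten years
    n_tr = cfg.treatment_cycles
    cost[:n_tr] += w_surv * c_treat
    util[:n_tr] += w_surv * u_treat * h
    occ_treat[:n_tr] += w_surv
    util[n_tr:n_cure] += w_surv * u_rem * h
    occ_rem[n_tr:n_cure] += w_surv
    util[n_cure:] += w_surv * 1.0 * h
    occ_cured[n_cure:] += w_surv

    alive = occ_treat + occ_rem + occ_prog + occ_cured
    return _StageStreams(cost, util, alive, occ_treat, occ_rem, occ_prog,
                         occ_cured, dead_inc)


def _future_weighted(values: np.ndarray, stream: np.ndarray) -> np.ndarray:
    """R[j] = sum_{i>=1} stream[i-1] * values[j+i] (truncated at len)."""
    T = len(values)
    c = np.convolve(stream, values[::-1])
    out = np.zeros(T)
    out[: T - 1] = c[T - 2 :: -1][: T - 1]
    return out


def _past_conv(masses: np.ndarray, stream: np.ndarray) -> np.ndarray:
    """P[t] = sum_{j<t} masses[j] * stream[t-j-1]."""
    T = len(masses)
    return np.convolve(masses, np.concatenate(([0.0], stream)))[:T]


@dataclass
class _ModelContext:
    """Arm-independent precomputation for one ParameterSet."""

    ages: np.ndarray
    p_on: np.ndarray
    q_bg: np.ndarray
    B: np.ndarray       # background survival through end of cycle t
    B_prev: np.ndarray  # shifted: survival through end of cycle t-1
    D: np.ndarray       # discount factor at end of cycle t
    streams: Mapping[str, _StageStreams]
    cost_dx: Mapping[str, np.ndarray]   # discounted post-dx cost by dx cycle
    qaly_dx: Mapping[str, np.ndarray]


def _build_context(params: ParameterSet) -> _ModelContext:
    cfg = params.config
    if math.isnan(params.background.a):
        raise ValidationError(
            "background mortality is uncalibrated (gompertz_a is not set); "
            "run calibrate_background_mortality first"
        )
    if cfg.n_cycles <= cfg.cure_cycles:
        raise ValidationError(
            "time horizon must exceed the ten-year cure window"
        )
    ages = cfg.ages()
    h = cfg.cycle_len
    p_on = np.array([params.incidence.cycle_prob(a, h) for a in ages])
    q_bg = params.background.cycle_probs(ages, h)
    B = np.cumprod(1.0 - q_bg)
    B_prev = np.concatenate(([1.0], B[:-1]))
    t_end = h * (np.arange(cfg.n_cycles) + 1)
    D = (1.0 + cfg.discount_rate) ** (-t_end)
    G = B * D

    streams = {s: _build_stage_streams(s, params) for s in STAGES}
    # post-diagnosis folding: a mass diagnosed in cycle j is thinned by
    # background survival from cycle j onward, i.e. B[j+i] / B[j-1]
    cost_dx = {}
    qaly_dx = {}
    for s, st in streams.items():
        cost_dx[s] = _future_weighted(G, st.cost) / B_prev
        qaly_dx[s] = _future_weighted(G, st.util) / B_prev
    return _ModelContext(ages, p_on, q_bg, B, B_prev, D, streams,
                         cost_dx, qaly_dx)


def post_diagnosis_value(
    stage: str,
    detection_mode: str,
    diagnosis_cycle: int,
    params: ParameterSet,
) -> tuple[float, float, np.ndarray]:
    """Expected discounted cost, QALYs and survival after one diagnosis.

    Expectation over the cancer-death density with the terminal-pathway
    override, net of background mortality, discounted to cohort entry.
    Accrual starts the cycle after diagnosis; the returned survival
    profile gives the probability of being alive at the end of each later
    cycle (index 0 = diagnosis cycle, survival 1 by convention).  The
    value depends on the detection mode only through the stage, which the
    caller has already drawn from that mode's stage distribution.
    """
    if detection_mode not in MODES:
        raise ValueError(f"unknown detection mode {detection_mode!r}")
    ctx = _build_context(params)
    j = diagnosis_cycle
    T = params.config.n_cycles
    if not (0 <= j < T):
        raise ValueError(f"diagnosis cycle {j} outside horizon [0, {T})")
    st = ctx.streams[stage]
    n = T - 1 - j
    profile = np.ones(T - j)
    profile[1:] = st.alive[:n] * ctx.B[j + 1 :] / ctx.B_prev[j]
    return (float(ctx.cost_dx[stage][j]), float(ctx.qaly_dx[stage][j]),
            profile)


# --------------------------------------------------------------------------
# Cohort evaluation
# --------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accruals for one arm."""

    arm: str
    ages: np.ndarray
    compartments: dict[str, np.ndarray]
    cost_cycle: np.ndarray   # discounted cost increments per cycle
    qaly_cycle: np.ndarray   # discounted QALY increments per cycle
    total_cost: float
    total_qaly: float
    incidence_by_65: float
    program_sensitivity: float
    stage_distribution: np.ndarray
    survival_to_65: float
    config: ModelConfig

    _ALIVE = ("well", "undetected", "dx_new", "treatment", "remission",
              "progressive", "cured")

    def alive(self) -> np.ndarray:
        return sum(self.compartments[c] for c in self._ALIVE)

    def survival_to_age(self, age: float) -> float:
        """Fraction of the cohort alive when reaching ``age``."""
        t = int(round((age - self.config.start_age) / self.config.cycle_len))
        if t <= 0:
            return 1.0
        return float(self.alive()[t - 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age": self.ages, **self.compartments})
        df["cost_discounted"] = self.cost_cycle
        df["qaly_discounted"] = self.qaly_cycle
        return df


def _detection_arrays(schedule: ScreeningSchedule, perf: ScreenPerformance,
                      ages: np.ndarray):
    """Per-cycle first-chance/second-chance sensitivities and specificity."""
    arm = schedule.arm
    ev = schedule.as_array()
    T = len(ev)
    mri_hi = schedule.config.mri_ages[1]
    se1 = np.zeros(T)
    sp = np.ones(T)
    pi2 = np.zeros(T)  # indexed by onset cycle; applies at the next cycle
    for t in range(T):
        name = _EVENT_NAMES[ev[t]]
        se1[t] = detection_probability(name, None, ages[t], perf, arm, mri_hi)
        sp[t] = _specificity(ev[t], ages[t], perf, arm, mri_hi)
        if t + 1 < T:
            nxt = _EVENT_NAMES[ev[t + 1]]
            prior = None if ev[t] == EVENT_NONE else name
            pi2[t] = detection_probability(nxt, prior, ages[t + 1], perf,
                                           arm, mri_hi)
    return ev, se1, sp, pi2


def _evaluate_arm(params: ParameterSet, schedule: ScreeningSchedule,
                  ctx: _ModelContext, full_trace: bool) -> CohortTrace | dict:
    cfg = params.config
    T = cfg.n_cycles
    h = cfg.cycle_len
    ages, p_on, q, B, D = ctx.ages, ctx.p_on, ctx.q_bg, ctx.B, ctx.D

    ev, se1, sp, pi2 = _detection_arrays(schedule, params.screen, ages)
    screened = ev != EVENT_NONE
    c_event = np.where(ev == EVENT_MRI, params.costs.c_mri,
                       np.where(ev == EVENT_MAM, params.costs.c_mam, 0.0))

    # --- pre-diagnosis propagation (closed form) -------------------------
    w_fac = (1.0 - p_on) * (1.0 - q)
    w_pre = np.concatenate(([1.0], np.cumprod(w_fac)[:-1]))  # well entering t
    onset = w_pre * p_on
    det0 = onset * se1                              # detected at onset cycle
    u1 = onset * (1.0 - se1) * (1.0 - q)            # undetected at cycle end
    det1 = np.zeros(T)                              # detected one cycle later
    det1[1:] = u1[:-1] * pi2[:-1]
    det2 = np.zeros(T)                              # clinical (non-screen)
    det2[1:] = u1[:-1] * (1.0 - pi2[:-1])

    det_mode = {
        "mri_detected": (det0 + det1) * (ev == EVENT_MRI),
        "mam_detected": (det0 + det1) * (ev == EVENT_MAM),
        "non_screen": det2,
    }
    det_all = det0 + det1 + det2
    m_stage = {}
    for s_idx, s in enumerate(STAGES):
        m_stage[s] = sum(det_mode[mode] * params.stage_dists[mode].p[s_idx]
                         for mode in MODES)

    # --- screening costs and false positives -----------------------------
    cancer_free = w_pre * (1.0 - p_on)
    u1_prev = np.concatenate(([0.0], u1[:-1]))
    attendees = np.where(screened, cancer_free + onset + u1_prev, 0.0)
    fp_mass = np.where(screened, cancer_free * (1.0 - sp), 0.0)
    workup_mass = fp_mass + det_all
    cost_cycle = attendees * c_event + workup_mass * params.costs.c_workup

    # --- pre-diagnosis QALYs (alive at cycle end accrue a full cycle) ----
    w_end = w_pre * w_fac
    dx_end = det_all * (1.0 - q)
    qaly_cycle = (h * (w_end + u1 + dx_end)
                  - workup_mass * params.utilities.workup_decrement)

    # --- post-diagnosis values -------------------------------------------
    cost_post = 0.0
    qaly_post = 0.0
    for s in STAGES:
        cost_post += float(m_stage[s] @ ctx.cost_dx[s])
        qaly_post += float(m_stage[s] @ ctx.qaly_dx[s])
    total_cost = float(cost_cycle @ D) + cost_post
    total_qaly = float(qaly_cycle @ D) + qaly_post

    # --- diagnostics ------------------------------------------------------
    t65 = min(T, int(round((65.0 - cfg.start_age) / h)))
    inc65 = float(onset[:t65].sum())
    screen_by_onset = det0 + u1 * pi2   # attributed to the onset cycle
    prog_sens = (float(screen_by_onset[:t65].sum()) / inc65 if inc65 > 0
                 else float("nan"))

    ev_next = np.concatenate((ev[1:], [EVENT_NONE]))
    mode_by_onset = {
        "mri_detected": (det0 * (ev == EVENT_MRI)
                         + u1 * pi2 * (ev_next == EVENT_MRI)),
        "mam_detected": (det0 * (ev == EVENT_MAM)
                         + u1 * pi2 * (ev_next == EVENT_MAM)),
        "non_screen": u1 * (1.0 - pi2),
    }
    stage_mix = np.zeros(4)
    for mode in MODES:
        w = float(mode_by_onset[mode][:t65].sum())
        stage_mix += w * np.asarray(params.stage_dists[mode].p)
    if stage_mix.sum() > 0:
        stage_mix = stage_mix / stage_mix.sum()

    # alive at the end of the cycle preceding age 65
    def alive_at(t: int) -> float:
        pre = w_end[t] + u1[t] + dx_end[t]
        post = 0.0
        for s in STAGES:
            mb = m_stage[s][:t] / ctx.B_prev[:t]
            post += float(mb @ ctx.streams[s].alive[t - 1 :: -1][:t]) * B[t]
        return pre + post

    surv65 = alive_at(t65 - 1) if t65 >= 1 else 1.0

    outcomes = {
        "cost": total_cost,
        "qaly": total_qaly,
        "incidence_by_65": inc65,
        "program_sensitivity": prog_sens,
        "stage_distribution": stage_mix,
        "survival_to_65": surv65,
    }
    if not full_trace:
        return outcomes

    # --- full per-cycle trace --------------------------------------------
    comp = {
        "well": w_end,
        "undetected": u1,
        "dx_new": dx_end,
        "treatment": np.zeros(T),
        "remission": np.zeros(T),
        "progressive": np.zeros(T),
        "cured": np.zeros(T),
    }
    dead_ca_inc = np.zeros(T)
    post_alive = np.zeros(T)
    cost_post_cycle = np.zeros(T)
    qaly_post_cycle = np.zeros(T)
    for s in STAGES:
        st = ctx.streams[s]
        mb = m_stage[s] / ctx.B_prev
        comp["treatment"] += _past_conv(mb, st.occ_treat) * B
        comp["remission"] += _past_conv(mb, st.occ_rem) * B
        comp["progressive"] += _past_conv(mb, st.occ_prog) * B
        comp["cured"] += _past_conv(mb, st.occ_cured) * B
        dead_ca_inc += _past_conv(mb, st.dead_ca_inc) * ctx.B_prev
        post_alive += _past_conv(mb, st.alive) * ctx.B_prev
        cost_post_cycle += _past_conv(mb, st.cost) * B
        qaly_post_cycle += _past_conv(mb, st.util) * B
    comp["dead_cancer"] = np.cumsum(dead_ca_inc)
    # background-death increments: everyone alive and not cancer-dying
    pre_exposed = w_pre * (1.0 - p_on) + onset + u1_prev
    comp["dead_other"] = np.cumsum(q * (pre_exposed + post_alive))

    return CohortTrace(
        arm=schedule.arm, ages=ages, compartments=comp,
        cost_cycle=(cost_cycle + cost_post_cycle) * D,
        qaly_cycle=(qaly_cycle + qaly_post_cycle) * D,
        total_cost=total_cost, total_qaly=total_qaly,
        incidence_by_65=inc65, program_sensitivity=prog_sens,
        stage_distribution=stage_mix, survival_to_65=surv65, config=cfg,
    )


def run_cohort(arm: str, params: ParameterSet,
               schedule: ScreeningSchedule | None = None) -> CohortTrace:
    """Evaluate one strategy arm, returning the full per-cycle trace."""
    if schedule is None:
        schedule = build_screening_schedule(arm, params.config)
    ctx = _build_context(params)
    return _evaluate_arm(params, schedule, ctx, full_trace=True)


def evaluate_strategies(params: ParameterSet) -> dict[str, dict]:
    """Fast paired evaluation of both arms on one ParameterSet.

    Shares the stage-stream precomputation between arms; used by the
    probabilistic sensitivity analysis loop.
    """
    ctx = _build_context(params)
    out = {}
    for arm in ARMS:
        schedule = build_screening_schedule(arm, params.config)
        out[arm] = _evaluate_arm(params, schedule, ctx, full_trace=False)
    return out


# --------------------------------------------------------------------------
# Incremental summary
# --------------------------------------------------------------------------

@dataclass
class OutcomeSummary:
    """Per-arm and incremental cost-effectiveness results."""

    cost: dict[str, float]
    qaly: dict[str, float]
    d_cost: float
    d_qaly: float
    icer: float | str
    incidence_by_65: dict[str, float]
    program_sensitivity: dict[str, float]
    stage_distribution: dict[str, np.ndarray]
    survival_to_65: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "cost": self.cost,
            "qaly": self.qaly,
            "incremental_cost": self.d_cost,
            "incremental_qaly": self.d_qaly,
            "icer": self.icer,
            "incidence_by_65": self.incidence_by_65,
            "program_sensitivity": self.program_sensitivity,
            "stage_distribution": {k: list(map(float, v))
                                   for k, v in self.stage_distribution.items()},
            "survival_to_65": self.survival_to_65,
        }


def icer_or_label(d_cost: float, d_qaly: float,
                  eps: float = 1e-12) -> float | str:
    """ICER, or a dominance label when the ratio is not meaningful."""
    if abs(d_cost) < eps and abs(d_qaly) < eps:
        return "equivalent"
    if d_qaly <= 0.0 and d_cost >= 0.0:
        return "dominated"
    if d_qaly >= 0.0 and d_cost <= 0.0:
        return "dominant"
    return d_cost / d_qaly


def summarize(trace_combined: CohortTrace,
              trace_mammo: CohortTrace) -> OutcomeSummary:
    """Incremental results of the combined arm over mammography alone."""
    d_cost = trace_combined.total_cost - trace_mammo.total_cost
    d_qaly = trace_combined.total_qaly - trace_mammo.total_qaly
    pick = lambda attr: {
        "combined": getattr(trace_combined, attr),
        "mammography_only": getattr(trace_mammo, attr),
    }
    return OutcomeSummary(
        cost=pick("total_cost"), qaly=pick("total_qaly"),
        d_cost=d_cost, d_qaly=d_qaly, icer=icer_or_label(d_cost, d_qaly),
        incidence_by_65=pick("incidence_by_65"),
        program_sensitivity=pick("program_sensitivity"),
        stage_distribution=pick("stage_distribution"),
        survival_to_65=pick("survival_to_65"),
    )
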