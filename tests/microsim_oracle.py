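"""Independent individual-level microsimulation of one strategy arm.

This is the correctness oracle for the expected-value cohort engine: it
simulates women one at a time through the same discrete-time rules
(onset, screening, detection, diagnosis, treatment/remission/progression,
cure, competing mortality) by sampling every transition, and accrues each
woman's discounted costs and QALYs directly.  With a large cohort its
per-arm means must agree with the cohort engine within Monte-Carlo error.

It deliberately shares no propagation code with the engine: state flow is
a per-woman state machine over numpy arrays, and accruals are written out
cycle by cycle from the model conventions (accrual to those alive at the
cycle end; screening/work-up costs and the work-up disutility at the
screen itself; no accrual in the death cycle).
"""

from __future__ import annotations

import numpy as np

from brcascreen.engine import (
    EVENT_MAM,
    EVENT_MRI,
    EVENT_NONE,
    _EVENT_NAMES,
    build_screening_schedule,
    detection_probability,
)
from brcascreen.parameters import MODES, STAGES, ParameterSet
from brcascreen.survival import death_density_by_cycle

WELL, UNDET, DIAG, DEAD_CA, DEAD_OTH = 0, 1, 2, 3, 4


def simulate_arm(arm: str, params: ParameterSet, n_women: int, seed: int):
    """Simulate ``n_women`` through one arm; return per-woman accruals.

    Returns a dict with per-woman ``cost`` and ``qaly`` arrays plus a few
    cohort diagnostics (cancers by 65, screen-detected by 65, alive at 65).
    """
    cfg = params.config
    T = cfg.n_cycles
    h = cfg.cycle_len
    ages = cfg.ages()
    rng = np.random.default_rng(seed)

    schedule = build_screening_schedule(arm, cfg)
    ev = schedule.as_array()
    mri_hi = cfg.mri_ages[1]

    p_on = np.array([params.incidence.cycle_prob(a, h) for a in ages])
    q_bg = params.background.cycle_probs(ages, h)
    t_end = h * (np.arange(T) + 1)
    disc = (1.0 + cfg.discount_rate) ** (-t_end)

    # per-cycle detection probabilities mirrored from the published rules
    se_first = np.zeros(T)
    se_second = np.zeros(T)  # applies at cycle t to onsets from t-1
    sp = np.ones(T)
    perf = params.screen
    for t in range(T):
        name = _EVENT_NAMES[ev[t]]
        se_first[t] = detection_probability(name, None, ages[t], perf, arm,
                                            mri_hi)
        if ev[t] != EVENT_NONE:
            if arm == "mammography_only":
                sp[t] = perf.mam_alone_band(ages[t]).sp
            elif ev[t] == EVENT_MRI:
                sp[t] = perf.sp_mri
            elif ages[t] > mri_hi + 0.5:
                sp[t] = perf.mam_alone_band(ages[t]).sp
            else:
                sp[t] = perf.sp_mam_in_combined
        if t >= 1:
            prior = (None if ev[t - 1] == EVENT_NONE
                     else _EVENT_NAMES[ev[t - 1]])
            se_second[t] = detection_probability(name, prior, ages[t], perf,
                                                 arm, mri_hi)
    c_event = np.where(ev == EVENT_MRI, params.costs.c_mri,
                       np.where(ev == EVENT_MAM, params.costs.c_mam, 0.0))

    # stage sampling tables per detection mode, death-cycle table per stage
    stage_cum = {m: np.cumsum(params.stage_dists[m].p) for m in MODES}
    death_cum = {}
    for s in STAGES:
        d = death_density_by_cycle(params.survival[s], cfg.cure_cycles, h)
        death_cum[s] = np.cumsum(np.append(d, 1.0 - d.sum()))
    c_treat = np.array([params.costs.treat_total[s] / cfg.treatment_cycles
                        for s in STAGES])
    u_treat = np.array([params.utilities.u_treat[s] for s in STAGES])
    c_eol = params.costs.eol_total / cfg.terminal_cycles
    u_prog = params.utilities.u_progression
    u_rem = params.utilities.u_remission
    du_workup = params.utilities.workup_decrement
    c_workup = params.costs.c_workup

    state = np.full(n_women, WELL, dtype=np.int8)
    onset = np.full(n_women, -1, dtype=np.int32)
    dx = np.full(n_women, -1, dtype=np.int32)
    death_k = np.zeros(n_women, dtype=np.int32)  # 0 = survivor path
    stage = np.full(n_women, -1, dtype=np.int8)
    cost = np.zeros(n_women)
    qaly = np.zeros(n_women)

    mode_of_event = {EVENT_MRI: "mri_detected", EVENT_MAM: "mam_detected"}
    t65 = int(round((65.0 - cfg.start_age) / h))
    screen_detected = np.zeros(n_women, dtype=bool)
    alive_65 = np.zeros(n_women, dtype=bool)

    def diagnose(idx: np.ndarray, mode: str, t: int) -> None:
        if idx.size == 0:
            return
        cum = stage_cum[mode]
        stage[idx] = np.searchsorted(cum, rng.random(idx.size))
        dx[idx] = t
        state[idx] = DIAG
        cost[idx] += c_workup * disc[t]
        qaly[idx] -= du_workup * disc[t]
        for s_idx, s in enumerate(STAGES):
            sub = idx[stage[idx] == s_idx]
            if sub.size:
                death_k[sub] = np.searchsorted(
                    death_cum[s], rng.random(sub.size)) + 1
        death_k[idx[death_k[idx] > cfg.cure_cycles]] = 0  # cured survivors

    for t in range(T):
        # 1. onset among well women (before the cycle's screen)
        well = np.flatnonzero(state == WELL)
        if p_on[t] > 0 and well.size:
            new = well[rng.random(well.size) < p_on[t]]
            state[new] = UNDET
            onset[new] = t

        # 2. screening: attendance, detection, false positives
        if ev[t] != EVENT_NONE:
            und = np.flatnonzero(state == UNDET)
            well = np.flatnonzero(state == WELL)
            cost[und] += c_event[t] * disc[t]
            cost[well] += c_event[t] * disc[t]
            first = und[onset[und] == t]
            second = und[onset[und] == t - 1]
            hit1 = first[rng.random(first.size) < se_first[t]]
            hit2 = second[rng.random(second.size) < se_second[t]]
            hits = np.concatenate([hit1, hit2])
            if ev[t] in mode_of_event:
                screen_detected[hits[onset[hits] < t65]] = True
                diagnose(hits, mode_of_event[ev[t]], t)
            fp = well[rng.random(well.size) < 1.0 - sp[t]]
            cost[fp] += c_workup * disc[t]
            qaly[fp] -= du_workup * disc[t]

        # 3. undetected for a full further cycle -> clinical diagnosis
        und = np.flatnonzero(state == UNDET)
        clinical = und[onset[und] == t - 1]
        diagnose(clinical, "non_screen", t)

        # 4. cancer death (takes precedence over background death)
        diag = np.flatnonzero(state == DIAG)
        dying = diag[(death_k[diag] >= 1)
                     & (t - dx[diag] == death_k[diag])]
        state[dying] = DEAD_CA

        # 5. background death among everyone still alive
        alive = np.flatnonzero((state == WELL) | (state == UNDET)
                               | (state == DIAG))
        bg = alive[rng.random(alive.size) < q_bg[t]]
        state[bg] = DEAD_OTH

        # 6. accruals for those alive at the cycle end
        healthy = np.flatnonzero((state == WELL) | (state == UNDET))
        qaly[healthy] += h * disc[t]
        diag = np.flatnonzero(state == DIAG)
        i = t - dx[diag]
        newly = diag[i == 0]
        qaly[newly] += h * disc[t]
        post = diag[i >= 1]
        ip = t - dx[post]
        k = death_k[post]
        in_prog = (k >= 4) & (ip >= k - 3)
        in_treat = ~in_prog & (ip <= cfg.treatment_cycles)
        in_rem = ~in_prog & ~in_treat & (ip <= cfg.cure_cycles)
        in_cured = ~in_prog & ~in_treat & ~in_rem
        sub = post[in_prog]
        cost[sub] += c_eol * disc[t]
        qaly[sub] += u_prog * h * disc[t]
        sub = post[in_treat]
        cost[sub] += c_treat[stage[sub]] * disc[t]
        qaly[sub] += u_treat[stage[sub]] * h * disc[t]
        qaly[post[in_rem]] += u_rem * h * disc[t]
        qaly[post[in_cured]] += h * disc[t]

        if t == t65 - 1:
            alive_65 = (state == WELL) | (state == UNDET) | (state == DIAG)

    return {
        "cost": cost,
        "qaly": qaly,
        "cancer_by_65": onset[(onset >= 0) & (onset < t65)].size / n_women,
        "screen_detected_by_65": screen_detected.sum() / n_women,
        "alive_at_65": alive_65.mean(),
    }
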