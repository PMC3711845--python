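"""Cohort engine: schedules, detection, accrual conventions, conservation
and limiting cases."""

import dataclasses

import numpy as np
import pytest

import brcascreen as bs
from brcascreen.engine import (
    EVENT_MAM,
    EVENT_MRI,
    EVENT_NONE,
    ScreeningSchedule,
    build_screening_schedule,
    detection_probability,
    false_positive_flow,
    icer_or_label,
    post_diagnosis_value,
)
from brcascreen.parameters import (
    STAGES,
    IncidenceSchedule,
    MamAloneBand,
    ScreenPerformance,
)
from brcascreen.survival import (
    death_density_by_cycle,
    terminal_pathway_allocation,
)


def _age_event(schedule, age):
    t = int(round((age - schedule.config.start_age)
                  / schedule.config.cycle_len))
    return schedule.events[t]


class TestSchedules:
    def test_combined_arm_layout(self, mean_params):
        sched = build_screening_schedule("combined", mean_params.config)
        assert sched.events[0] == EVENT_MRI          # first event: MRI at 25
        assert _age_event(sched, 27.0) == EVENT_MRI  # annual MRI below 30
        assert _age_event(sched, 27.5) == EVENT_NONE
        for age in np.arange(30.0, 64.5, 0.5):      # alternation in 30-64
            expected = EVENT_MRI if age == int(age) else EVENT_MAM
            assert _age_event(sched, age) == expected
        assert _age_event(sched, 70.5) == EVENT_MAM  # annual mammography
        assert _age_event(sched, 70.0) == EVENT_NONE
        assert _age_event(sched, 80.5) == EVENT_NONE  # screening has ended

    def test_mammography_alone_layout(self, mean_params):
        sched = build_screening_schedule("mammography_only",
                                         mean_params.config)
        assert _age_event(sched, 27.0) == EVENT_NONE  # outside 30-79
        assert _age_event(sched, 30.0) == EVENT_MAM
        assert _age_event(sched, 30.5) == EVENT_NONE
        assert _age_event(sched, 79.0) == EVENT_MAM
        assert _age_event(sched, 80.0) == EVENT_NONE
        codes = np.asarray(sched.events)
        assert not np.any(codes == EVENT_MRI)

    def test_unknown_arm_rejected(self, mean_params):
        with pytest.raises(ValueError):
            build_screening_schedule("both", mean_params.config)


class TestDetectionAndFalsePositives:
    def test_conditional_after_opposite_modality_miss(self, mean_params):
        p = detection_probability("mri", "mammogram", 45.0,
                                  mean_params.screen)
        assert p == pytest.approx(0.9016, abs=1e-3)
        p = detection_probability("mammogram", "mri", 45.0,
                                  mean_params.screen)
        assert p == pytest.approx(0.7391, abs=1e-3)

    def test_no_screen_no_detection(self, mean_params):
        assert detection_probability("none", None, 40.0,
                                     mean_params.screen) == 0.0

    def test_mammography_alone_uses_age_bands(self, mean_params):
        p = detection_probability("mammogram", None, 45.0,
                                  mean_params.screen, "mammography_only")
        assert p == pytest.approx(0.70)
        # above the last printed band the last band's value is reused
        p = detection_probability("mammogram", None, 75.0,
                                  mean_params.screen, "mammography_only")
        assert p == pytest.approx(0.84)

    def test_false_positive_flow_published_arithmetic(self, mean_params):
        cost, dq = false_positive_flow("mri", mean_params.screen,
                                       mean_params.costs,
                                       mean_params.utilities)
        assert cost == pytest.approx(0.14 * 187, abs=1e-9)
        assert dq == pytest.approx(0.14 * 0.013 * 14 / 365.25, abs=1e-7)
        cost, _ = false_positive_flow("mammogram", mean_params.screen,
                                      mean_params.costs,
                                      mean_params.utilities)
        assert cost == pytest.approx(0.05 * 187, abs=1e-9)
        assert false_positive_flow("none", mean_params.screen,
                                   mean_params.costs,
                                   mean_params.utilities) == (0.0, 0.0)

    def test_perfect_specificity_is_free(self, mean_params):
        perf = dataclasses.replace(mean_params.screen, sp_mri=1.0)
        assert false_positive_flow("mri", perf, mean_params.costs,
                                   mean_params.utilities) == (0.0, 0.0)


def brute_force_post_dx(stage, j, params):
    """Spreadsheet-style path-by-path expectation, written independently."""
    cfg = params.config
    h, T = cfg.cycle_len, cfg.n_cycles
    q = params.background.cycle_probs(cfg.ages(), h)
    d = death_density_by_cycle(params.survival[stage], cfg.cure_cycles, h)
    u = params.utilities
    paths = [(k, d[k - 1]) for k in range(1, cfg.cure_cycles + 1)]
    paths.append((None, 1.0 - d.sum()))
    cost = qaly = 0.0
    for k, wk in paths:
        if wk == 0.0:
            continue
        prog = (set(terminal_pathway_allocation(k).progressive_cycles)
                if k is not None else set())
        bsurv = 1.0 - q[j]
        i = 1
        while j + i < T and (k is None or i < k):
            t = j + i
            bsurv *= 1.0 - q[t]
            if i in prog:
                c, uu = params.costs.eol_total / 3.0, u.u_progression
            elif i <= 3:
                c, uu = params.costs.treat_total[stage] / 3.0, \
                    u.u_treat[stage]
            elif i <= cfg.cure_cycles:
                c, uu = 0.0, u.u_remission
            else:
                c, uu = 0.0, 1.0
            disc = (1 + cfg.discount_rate) ** (-h * (t + 1))
            cost += wk * bsurv * c * disc
            qaly += wk * bsurv * uu * h * disc
            i += 1
    return cost, qaly


class TestPostDiagnosisValue:
    @pytest.mark.parametrize("stage", STAGES)
    @pytest.mark.parametrize("dx_cycle", [0, 40, 110])
    def test_matches_independent_path_expectation(self, mean_params, stage,
                                                  dx_cycle):
        cost, qaly, _ = post_diagnosis_value(stage, "non_screen", dx_cycle,
                                             mean_params)
        b_cost, b_qaly = brute_force_post_dx(stage, dx_cycle, mean_params)
        assert cost == pytest.approx(b_cost, rel=1e-10, abs=1e-9)
        assert qaly == pytest.approx(b_qaly, rel=1e-10, abs=1e-12)

    def test_in_situ_closed_form_no_discount_no_background(self, mean_params):
        """In-situ disease never kills: treatment, remission, then cured."""
        params = dataclasses.replace(
            mean_params,
            config=dataclasses.replace(mean_params.config, discount_rate=0.0),
            background=dataclasses.replace(mean_params.background, a=1e-300),
        )
        j = 10
        cost, qaly, profile = post_diagnosis_value("in_situ", "mri_detected",
                                                   j, params)
        T = params.config.n_cycles
        u = params.utilities
        expected_qaly = (3 * 0.5 * u.u_treat["in_situ"]
                         + 17 * 0.5 * u.u_remission
                         + (T - 1 - j - 20) * 0.5 * 1.0)
        assert cost == pytest.approx(3427.0, rel=1e-12)
        assert qaly == pytest.approx(expected_qaly, rel=1e-12)
        assert np.all(profile == 1.0)

    def test_distant_end_of_life_weighting(self, mean_params):
        """End-of-life cost is carried by the 1 - S(10y) who die of cancer."""
        params = dataclasses.replace(
            mean_params,
            config=dataclasses.replace(mean_params.config, discount_rate=0.0),
            background=dataclasses.replace(mean_params.background, a=1e-300),
        )
        cost, _, _ = post_diagnosis_value("distant", "non_screen", 0, params)
        no_eol = dataclasses.replace(
            params, costs=dataclasses.replace(params.costs, eol_total=0.0))
        cost_no_eol, _, _ = post_diagnosis_value("distant", "non_screen", 0,
                                                 no_eol)
        d = death_density_by_cycle(params.survival["distant"], 20, 0.5)
        assert d.sum() == pytest.approx(1.0 - 0.102, abs=1e-3)
        # deaths within 3 cycles skip progressive disease entirely; every
        # later death carries the full end-of-life total
        assert cost - cost_no_eol == pytest.approx(
            params.costs.eol_total * d[3:].sum(), rel=1e-12)


class TestCohortInvariants:
    def test_occupancy_conserved_every_cycle(self, base_traces):
        for trace in base_traces:
            total = trace.alive() + trace.compartments["dead_cancer"] \
                + trace.compartments["dead_other"]
            assert np.abs(total - 1.0).max() < 1e-10
            for comp in trace.compartments.values():
                assert np.all(comp >= -1e-15)

    def test_totals_equal_cycle_sums(self, base_traces):
        for trace in base_traces:
            assert trace.total_cost == pytest.approx(trace.cost_cycle.sum(),
                                                     rel=1e-9)
            assert trace.total_qaly == pytest.approx(trace.qaly_cycle.sum(),
                                                     rel=1e-9)

    def test_base_case_magnitudes(self, base_summary):
        s = base_summary
        assert s.cost["mammography_only"] == pytest.approx(5201, rel=0.10)
        assert s.qaly["mammography_only"] == pytest.approx(22.57, rel=0.02)
        assert s.d_cost > 0
        assert isinstance(s.icer, float)

    def test_zero_discount_equals_undiscounted_sum(self, mean_params):
        """At rate 0 QALYs equal expected (quality-weighted) life-years."""
        params = dataclasses.replace(
            mean_params,
            config=dataclasses.replace(mean_params.config, discount_rate=0.0),
            incidence=IncidenceSchedule(tuple(
                (lo, hi, 0.0) for lo, hi, _ in mean_params.incidence.bands)),
            screen=ScreenPerformance.from_marginals(
                0.94, 0.77, 0.77, 1.0, 0.39, 1.0,
                [MamAloneBand(30, 40, 0.63, 1.0),
                 MamAloneBand(40, 70, 0.70, 1.0)]),
        )
        trace = bs.run_cohort("mammography_only", params)
        q = params.background.cycle_probs(params.config.ages(), 0.5)
        life_years = 0.5 * np.cumprod(1.0 - q).sum()
        assert trace.total_qaly == pytest.approx(life_years, rel=1e-12)

    def test_zero_incidence_limit(self, mean_params):
        """No cancer: MRI arm pays for screens and false positives for
        nothing, so it is strictly costlier and (weakly) less effective."""
        params = dataclasses.replace(
            mean_params,
            incidence=IncidenceSchedule(tuple(
                (lo, hi, 0.0) for lo, hi, _ in mean_params.incidence.bands)))
        comb = bs.run_cohort("combined", params)
        mam = bs.run_cohort("mammography_only", params)
        assert comb.incidence_by_65 == 0.0
        assert comb.total_cost > mam.total_cost
        assert comb.total_qaly <= mam.total_qaly
        assert mam.total_qaly - comb.total_qaly < 0.01  # only FP decrements

    def test_perfect_screening_limit(self, mean_params):
        perfect = ScreenPerformance.from_marginals(
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
            [MamAloneBand(30, 70, 1.0, 1.0)])
        params = dataclasses.replace(mean_params, screen=perfect)
        trace = bs.run_cohort("combined", params)
        # not exactly 1: a sliver of the cohort dies of other causes in the
        # half-cycle between onset and the next scheduled screen
        assert trace.program_sensitivity == pytest.approx(1.0, abs=1e-4)

    def test_aligned_arms_are_identical(self, mean_params):
        """With identical tests and schedules the arms coincide exactly."""
        flat_bands = [MamAloneBand(30, 70, 0.39, 0.95)]
        params = dataclasses.replace(
            mean_params,
            screen=ScreenPerformance.from_marginals(
                0.94, 0.77, 0.77, 0.86, 0.39, 0.95, flat_bands))
        mam_sched = build_screening_schedule("mammography_only",
                                             params.config)
        aligned = ScreeningSchedule(arm="combined", events=mam_sched.events,
                                    config=params.config)
        comb = bs.run_cohort("combined", params, schedule=aligned)
        mam = bs.run_cohort("mammography_only", params)
        assert comb.total_cost == pytest.approx(mam.total_cost, rel=1e-12)
        assert comb.total_qaly == pytest.approx(mam.total_qaly, rel=1e-12)

    def test_combined_program_sensitivity_dominates(self, base_traces):
        comb, mam = base_traces
        assert comb.program_sensitivity > mam.program_sensitivity

    def test_horizon_choice_is_immaterial(self, spec):
        icers = {}
        for horizon in (95.0, 100.0):
            (_, icers[horizon]), = bs.one_way_sensitivity(
                spec, "model.horizon_age", [horizon])
        assert abs(icers[95.0] - icers[100.0]) / icers[100.0] < 0.005


class TestSummaryLabels:
    def test_equivalent_traces(self, base_traces):
        comb, _ = base_traces
        s = bs.summarize(comb, comb)
        assert s.icer == "equivalent"
        assert s.d_cost == 0.0 and s.d_qaly == 0.0

    @pytest.mark.parametrize("d_cost,d_qaly,expected", [
        (100.0, -0.01, "dominated"),
        (100.0, 0.0, "dominated"),
        (-100.0, 0.01, "dominant"),
        (5000.0, 0.1, 50000.0),
    ])
    def test_dominance_labels(self, d_cost, d_qaly, expected):
        assert icer_or_label(d_cost, d_qaly) == expected
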