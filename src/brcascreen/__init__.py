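"""Cost-effectiveness of MRI + mammography screening in BRCA1/2 carriers.

A Markov cohort model (6-month cycles, ages 25 to the lifetime horizon)
comparing annual MRI plus mammography screening against annual
mammography alone, with calibrated parameter-uncertainty distributions,
probabilistic sensitivity analysis, acceptability curves and one-way
sensitivity analysis.
"""

from __future__ import annotations

__version__ = "0.1.0"

from dataclasses import replace

from .parameters import (
    STAGES,
    MODES,
    DistributionSpec,
    ParameterSet,
    ParameterSpec,
    band_risk_to_cycle_prob,
    beta_from_mean_ci,
    derive_conditional_sensitivities,
    dirichlet_from_stage_row,
    gamma_from_mean_ci,
    load_default_spec,
    load_parameter_spec,
    default_config_text,
)
from .survival import (
    BackgroundMortality,
    WeibullSpec,
    calibrate_background_mortality,
    death_density_by_cycle,
    fit_weibull_two_points,
    terminal_pathway_allocation,
)
from .engine import (
    CohortTrace,
    OutcomeSummary,
    ScreeningSchedule,
    build_screening_schedule,
    detection_probability,
    evaluate_strategies,
    false_positive_flow,
    post_diagnosis_value,
    run_cohort,
    summarize,
)
from .uncertainty import (
    CEACPoint,
    PSAResult,
    TornadoEntry,
    compute_ceac,
    one_way_sensitivity,
    run_psa,
    sample_parameter_set,
    set_param,
    tornado,
)


def calibrate_spec(spec: ParameterSpec) -> ParameterSpec:
    """Return ``spec`` with the background-mortality level calibrated.

    If the configuration already carries a Gompertz level, it is kept.
    """
    import math

    if not math.isnan(spec.background.a):
        return spec
    params = replace(spec.mean_parameter_set(),
                     background=replace(spec.background, a=1e-5))
    bg = calibrate_background_mortality(
        spec.background.target, params, b=spec.background.b
    )
    return replace(spec, background=bg)


def load_calibrated_spec(config_text: str | None = None) -> ParameterSpec:
    """Load a configuration (default if None) and calibrate mortality."""
    spec = (load_default_spec() if config_text is None
            else load_parameter_spec(config_text))
    return calibrate_spec(spec)
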