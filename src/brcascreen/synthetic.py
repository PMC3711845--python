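"""Synthetic stand-ins for the unavailable patient-level source data.

The model's cost and survival inputs were originally calibrated from
administrative records: per-patient treatment costs over three 6-month
intervals after diagnosis (a cancer-agency billing extract, n = 68) and
registry survival with linked vital-statistics follow-up.  Neither
dataset can be shipped, so this module generates synthetic records with
the same structure — gamma-distributed interval costs, Weibull event
times with administrative right censoring — and provides the matching
maximum-likelihood fits, so the calibration stages can be exercised
end-to-end and validated by parameter recovery.

The interval split of treatment costs is unpublished; the generator uses
a front-loaded Dirichlet share (most cost in months 1-6), which is a
stand-in and independent of the model's equal-thirds allocation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import WeibullFitter
from scipy import stats

from .parameters import STAGES, DistributionSpec
from .survival import WeibullSpec

# Dirichlet concentration for the three 6-month interval cost shares
# (front-loaded: surgery and most systemic therapy fall in months 1-6).
_INTERVAL_ALPHA = (6.0, 3.0, 2.0)

COST_COLUMNS = ("patient_id", "stage", "cost_m1_6", "cost_m7_12",
                "cost_m13_18", "died", "eol_m1_6", "eol_m7_12", "eol_m13_18")
SURV_COLUMNS = ("patient_id", "stage", "time_years", "event")


def generate_cost_records(
    stage_mix: Mapping[str, float],
    gamma_specs: Mapping[str, DistributionSpec],
    n: int,
    seed: int,
    *,
    eol_spec: DistributionSpec | None = None,
    death_prob: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Patient-level treatment-cost records over three 6-month intervals.

    Each patient's 18-month total is drawn from their stage's gamma
    distribution and split across intervals by a Dirichlet share.  When an
    end-of-life gamma and per-stage death probabilities are supplied, the
    flagged decedents also carry end-of-life interval costs for their last
    18 months.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stages = list(stage_mix)
    probs = np.array([stage_mix[s] for s in stages], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("stage mix must be non-negative with positive sum")
    probs = probs / probs.sum()
    for s in stages:
        if gamma_specs[s].family != "gamma":
            raise ValueError(f"stage {s!r} needs a gamma DistributionSpec")

    rng = np.random.default_rng(seed)
    stage_idx = rng.choice(len(stages), size=n, p=probs)
    totals = np.empty(n)
    for i, s in enumerate(stages):
        mask = stage_idx == i
        k, theta = gamma_specs[s].params
        totals[mask] = rng.gamma(k, theta, size=int(mask.sum()))
    shares = rng.dirichlet(_INTERVAL_ALPHA, size=n)
    interval_costs = totals[:, None] * shares

    died = np.zeros(n, dtype=bool)
    eol = np.zeros((n, 3))
    if eol_spec is not None and death_prob is not None:
        p_death = np.array([death_prob.get(stages[i], 0.0)
                            for i in stage_idx])
        died = rng.random(n) < p_death
        n_dead = int(died.sum())
        if n_dead:
            k, theta = eol_spec.params
            eol_tot = rng.gamma(k, theta, size=n_dead)
            eol_shares = rng.dirichlet(_INTERVAL_ALPHA[::-1], size=n_dead)
            eol[died] = eol_tot[:, None] * eol_shares

    return pd.DataFrame({
        "patient_id": np.arange(n),
        "stage": [stages[i] for i in stage_idx],
        "cost_m1_6": interval_costs[:, 0],
        "cost_m7_12": interval_costs[:, 1],
        "cost_m13_18": interval_costs[:, 2],
        "died": died,
        "eol_m1_6": eol[:, 0],
        "eol_m7_12": eol[:, 1],
        "eol_m13_18": eol[:, 2],
    })


def fit_gamma_mle(records: pd.DataFrame, stage: str) -> DistributionSpec:
    """Maximum-likelihood gamma fit to one stage's 18-month totals."""
    sub = records[records["stage"] == stage]
    totals = (sub["cost_m1_6"] + sub["cost_m7_12"] + sub["cost_m13_18"]
              ).to_numpy()
    totals = totals[totals > 0]
    if len(totals) < 2:
        raise ValueError(
            f"need at least 2 positive-cost records for stage {stage!r}"
        )
    if np.ptp(totals) == 0:
        raise ValueError(
            f"degenerate cost sample for stage {stage!r}: all values equal"
        )
    shape, _, scale = stats.gamma.fit(totals, floc=0.0)
    mean = shape * scale
    return DistributionSpec("gamma", (float(shape), float(scale)),
                            source=(float(mean), float(np.min(totals)),
                                    float(np.max(totals))))


def generate_survival_records(
    weibull_specs: Mapping[str, WeibullSpec],
    censor_time: float,
    n: int,
    seed: int,
    stage_mix: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Registry-style survival records with administrative censoring.

    Event times are drawn from each stage's Weibull; follow-up is cut at
    ``censor_time`` years (a fixed calendar window), producing
    right-censored records.  Degenerate (no-death) stages yield fully
    censored records.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if censor_time <= 0:
        raise ValueError("censor_time must be positive")
    stages = list(weibull_specs)
    if stage_mix is None:
        probs = np.full(len(stages), 1.0 / len(stages))
    else:
        probs = np.array([stage_mix[s] for s in stages], dtype=float)
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    stage_idx = rng.choice(len(stages), size=n, p=probs)
    times = np.full(n, np.inf)
    for i, s in enumerate(stages):
        mask = stage_idx == i
        spec = weibull_specs[s]
        if spec.degenerate:
            continue
        times[mask] = spec.scale * rng.weibull(spec.shape,
                                               size=int(mask.sum()))
    event = times <= censor_time
    obs = np.where(event, times, censor_time)
    # guard against zero follow-up times, which likelihoods reject
    obs = np.maximum(obs, 1e-9)
    return pd.DataFrame({
        "patient_id": np.arange(n),
        "stage": [stages[i] for i in stage_idx],
        "time_years": obs,
        "event": event,
    })


def fit_weibull_mle(records: pd.DataFrame, stage: str) -> WeibullSpec:
    """Censoring-aware maximum-likelihood Weibull fit for one stage."""
    sub = records[records["stage"] == stage]
    if int(sub["event"].sum()) < 2:
        raise ValueError(
            f"need at least 2 observed deaths to fit stage {stage!r}"
        )
    wf = WeibullFitter()
    wf.fit(sub["time_years"].to_numpy(), sub["event"].to_numpy())
    return WeibullSpec(shape=float(wf.rho_), scale=float(wf.lambda_),
                       stage=stage)
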