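"""Run manifests, tabular exports, validation checks and figures."""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import CohortTrace, OutcomeSummary
from .parameters import ParameterSpec
from .uncertainty import CEACPoint, PSAResult, TornadoEntry


def build_manifest(spec: ParameterSpec, *, seed: int | None = None,
                   extra: Mapping | None = None) -> dict:
    """Everything needed to reproduce a run bit-identically."""
    params = spec.mean_parameter_set()
    manifest = {
        "package_version": __version__,
        "config_fingerprint": spec.fingerprint(),
        "seed": seed,
        "currency": spec.raw_config.get("meta", {}).get("currency",
                                                        "2008 CAD"),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "calibration": {
            "background_mortality": {
                "gompertz_a": params.background.a,
                "gompertz_b": params.background.b,
                "target": params.background.target,
            },
            "weibull": {
                s: {"shape": w.shape, "scale": w.scale,
                    "degenerate": w.degenerate}
                for s, w in params.survival.items()
            },
            "conditional_sensitivities": {
                "se_mri_given_mam_fn": params.screen.se_mri_given_mam_fn,
                "se_mam_given_mri_fn": params.screen.se_mam_given_mri_fn,
            },
        },
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(path: Path, manifest: Mapping) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=str) + "\n")


def write_trace(path: Path, trace: CohortTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_summary(path: Path, summary: OutcomeSummary) -> None:
    path.write_text(json.dumps(summary.to_dict(), indent=2, default=float)
                    + "\n")


def write_psa_draws(path: Path, psa: PSAResult) -> None:
    psa.draws.to_csv(path, index=False)


def write_ceac(path: Path, ceac: Sequence[CEACPoint]) -> None:
    pd.DataFrame([asdict(p) for p in ceac]).to_csv(path, index=False)


def write_tornado(path: Path, entries: Sequence[TornadoEntry]) -> None:
    pd.DataFrame([asdict(e) for e in entries]).to_csv(path, index=False)


def validate_model(spec: ParameterSpec) -> tuple[dict, bool]:
    """Check mean-parameter outputs against the packaged reference values.

    Returns (report, all_passed); tolerances come from the configuration's
    ``validation_targets`` section.
    """
    from .engine import run_cohort

    targets = spec.raw_config.get("validation_targets", {})
    comb = run_cohort("combined", spec.mean_parameter_set())
    mam = run_cohort("mammography_only", spec.mean_parameter_set())
    computed = {
        "cumulative_incidence_by_65": 100.0 * mam.incidence_by_65,
        "program_sensitivity_combined": 100.0 * comb.program_sensitivity,
        "program_sensitivity_mammography": 100.0 * mam.program_sensitivity,
        "survival_to_65_combined": 100.0 * comb.survival_to_65,
        "survival_to_65_mammography": 100.0 * mam.survival_to_65,
    }
    report = {}
    all_ok = True
    for key, value in computed.items():
        entry = {"computed": round(value, 2)}
        if key in targets:
            ref = float(targets[key]["value"])
            tol = float(targets[key]["tol"])
            ok = abs(value - ref) <= tol
            entry.update(reference=ref, tolerance=tol,
                         status="pass" if ok else "fail")
            all_ok = all_ok and ok
        else:
            entry["status"] = "no-reference"
        report[key] = entry
    return report, all_ok


# --------------------------------------------------------------------------
# Figures (optional; all writers take a path and save a PNG/PDF)
# --------------------------------------------------------------------------

def _ellipse_points(x: np.ndarray, y: np.ndarray, n_sd: float = 2.4477):
    """95% normal-theory ellipse of a scatter (chi2_2 0.95 quantile)."""
    mu = np.array([x.mean(), y.mean()])
    cov = np.cov(x, y)
    vals, vecs = np.linalg.eigh(cov)
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    pts = vecs @ (np.sqrt(np.maximum(vals, 0))[:, None] * circle) * n_sd
    return mu[0] + pts[0], mu[1] + pts[1]


def plot_ce_plane(path: Path, psa: PSAResult) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = psa.draws["d_qaly"].to_numpy()
    y = psa.draws["d_cost"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, s=4, alpha=0.25, linewidths=0)
    ex, ey = _ellipse_points(x, y)
    ax.plot(ex, ey, color="black", lw=1.2)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (2008 CAD)")
    ax.set_title("Cost-effectiveness plane: MRI + mammography vs mammography")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(path: Path, ceac: Sequence[CEACPoint]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in ceac], [p.prob_cost_effective for p in ceac],
            marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (CAD per QALY)")
    ax.set_ylabel("P(MRI screening cost-effective)")
    ax.set_ylim(0, 1)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(path: Path, entries: Sequence[TornadoEntry],
                 base_icer: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = [e for e in entries if np.isfinite(e.width)]
    names = [e.parameter for e in finite][::-1]
    lows = [min(e.icer_low, e.icer_high) for e in finite][::-1]
    highs = [max(e.icer_low, e.icer_high) for e in finite][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(finite), 4) + 1.5))
    ax.barh(names, [h - l for l, h in zip(lows, highs)], left=lows,
            color="#4878d0")
    ax.axvline(base_icer, color="black", lw=1, ls="--",
               label=f"base case {base_icer:,.0f}")
    ax.set_xlabel("ICER (CAD per QALY)")
    ax.set_title("One-way sensitivity of the ICER")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
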