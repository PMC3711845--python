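# brcascreen

A decision-analytic Markov cohort model of breast-cancer screening for
women carrying *BRCA1*/*BRCA2* mutations, who face a 10-year cancer risk
of up to 20% in midlife. The package compares two programmes offered in
practice — **annual MRI plus annual mammography** (alternating every six
months) versus **annual mammography alone** — and asks what the extra
sensitivity of MRI buys, per dollar, over a woman's lifetime. It is
written for health-economics and screening-policy analysts who want a
transparent, fully scripted, testable version of this class of model:
every input is a published mean with a 95% CI, every calibration is
code, and every published headline number is recomputed, not copied.

## The model

A cohort enters at age 25 and is followed in 6-month cycles to age 100.
Each cycle a well woman may develop a first breast cancer with the
age-banded probability `p_c = 1 − (1 − risk₁₀)^(1/20)`. An incident
cancer is screened at that cycle's event (MRI or mammography); if missed
it gets one further chance in the next cycle — using the *conditional*
sensitivity of the second modality given the first's false negative,
derived from the marginal and combined sensitivities via the
joint-detection identity

    joint = se_MRI + se_mam − se_either,
    se_MRI|mam⁻ = (se_MRI − joint) / (1 − se_mam)

— and otherwise surfaces clinically with the historical (less
favourable) stage distribution. Stage at diagnosis is Dirichlet by mode
of detection; stage-specific survival is Weibull, calibrated in closed
form through the published 5- and 10-year survival anchors, with a cure
rule at 10 years. Deaths more than 18 months after diagnosis pass
through 3 cycles of progressive disease (end-of-life costs, utility
0.38) before death. Competing mortality is Gompertz, its level
calibrated by bisection so all-cause mortality by 65 matches the
published validation figure. Costs (2008 CAD) and utilities accrue per
cycle, discounted at 3.5%/yr; false positives incur a diagnostic
work-up and a two-week utility decrement.

Strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔE ($ per QALY gained). Parameter uncertainty is propagated by
Monte Carlo (Beta for probabilities/utilities, Gamma for costs,
Dirichlet for stage rows, each calibrated to the printed mean and CI)
with both arms evaluated on every draw; decision uncertainty is
summarised on the cost-effectiveness plane and as a CEAC under the
net-monetary-benefit rule.

## Worked example

```python
import brcascreen as bs

spec = bs.load_calibrated_spec()          # packaged inputs + calibration
params = spec.mean_parameter_set()
summary = bs.summarize(bs.run_cohort("combined", params),
                       bs.run_cohort("mammography_only", params))
```

Running `python examples/01_base_case.py` prints:

```
Per-woman discounted lifetime results (2008 CAD, 3.5%/yr):
  mammography_only   cost $   5,225   QALYs 22.914
  combined           cost $  10,365   QALYs 23.021
  incremental        cost $   5,141   QALYs 0.1071
  ICER               $47,979 per QALY gained

Screening-programme effectiveness (cohort entering at 25):
  cumulative breast-cancer incidence by 65: 44.0%
  mammography_only   programme sensitivity 72.8%   survival to 65 79.1%
  combined           programme sensitivity 93.1%   survival to 65 80.1%
```

Adding MRI roughly doubles lifetime screening spending and detects ~93%
rather than ~73% of cancers arising before 65 at an earlier stage,
buying ~0.11 discounted QALYs per woman at ~$48,000 per QALY — near the
conventional funding range, and (see `examples/03_one_way_and_tornado.py`)
swinging from ~$35,000 to ~$121,000/QALY as the MRI price moves from
$200 to $700 per scan.

Other entry points: `examples/02_psa_and_ceac.py` (probabilistic
sensitivity analysis and the acceptability curve),
`examples/04_calibration_recovery.py` (gamma/Weibull calibration on
synthetic patient-level records), and a CLI mirroring the library:

```bash
brcascreen run --out results/
brcascreen psa --n 10000 --seed 1 --out results/
brcascreen owsa --parameter costs.c_mri --lo 200 --hi 700 --out results/
brcascreen validate
```

All inputs live in one YAML document
(`src/brcascreen/data/default_config.yaml`); pass `--config` or
`bs.load_parameter_spec(text)` to study variants.

## Layout

- `src/brcascreen/parameters.py` — input types; Beta/Gamma/Dirichlet
  calibration from printed means and CIs; configuration loading.
- `src/brcascreen/survival.py` — two-point Weibull calibration, death
  densities, terminal-pathway rule, Gompertz competing mortality.
- `src/brcascreen/engine.py` — the cohort engine (screening schedules,
  detection logic, discounted accrual, traces, incremental summary).
- `src/brcascreen/uncertainty.py` — PSA, CEAC, one-way SA, tornado.
- `src/brcascreen/synthetic.py` — synthetic patient-level cost/survival
  records and the matching maximum-likelihood refits.
- `src/brcascreen/reporting.py`, `cli.py` — manifests, exports, figures,
  command-line wrappers.
- `docs/methods.md` — modelling assumptions, conventions and limits.
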