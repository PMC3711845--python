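# Default model configuration: annual MRI + mammography vs annual mammography
# alone for BRCA1/2 mutation carriers, British Columbia health-system
# perspective. All monetary values are 2008 Canadian dollars.
meta:
  currency: "2008 CAD"
  description: >
    Markov cohort model of breast-cancer screening in BRCA1/2 mutation
    carriers: published incidence, screen performance, stage distributions,
    interval survival, unit costs and utilities.

model:
  start_age: 25
  horizon_age: 100
  cycle_length_years: 0.5
  discount_rate: 0.035
  mri_ages: [25, 64]
  mam_ages: [30, 79]
  treatment_cycles: 3
  cure_cycles: 20
  terminal_cycles: 3

background_mortality:
  # Gompertz hazard a*exp(b*age); the level a is calibrated so that all-cause
  # mortality by target_age in the mammography-alone arm matches the target.
  gompertz_b: 0.09
  gompertz_a: null
  target_cum_mortality: 0.209
  target_age: 65

incidence:
  # 10-year risk of a first breast cancer, by age band.
  - {ages: [20, 30], risk10: 0.015, ci: [0.011, 0.019]}
  - {ages: [30, 40], risk10: 0.086, ci: [0.069, 0.11]}
  - {ages: [40, 50], risk10: 0.18, ci: [0.14, 0.23]}
  - {ages: [50, 60], risk10: 0.20, ci: [0.17, 0.25]}
  - {ages: [60, 70], risk10: 0.18, ci: [0.15, 0.22]}

screening:
  combined:
    # Meta-analytic performance of the alternating MRI/mammography programme.
    se_both: {mean: 0.94, ci: [0.90, 0.97]}
    sp_both: {mean: 0.77, ci: [0.75, 0.80]}
    se_mri: {mean: 0.77, ci: [0.70, 0.84]}
    sp_mri: {mean: 0.86, ci: [0.81, 0.92]}
    se_mam: {mean: 0.39, ci: [0.37, 0.41]}
    sp_mam: {mean: 0.95, ci: [0.93, 0.97]}
  mammography_alone:
    # Age-specific mammography performance (also used for mammography offered
    # past the MRI age range in the combined arm).
    - {ages: [30, 40], se: {mean: 0.63, ci: [0.42, 0.85]}, sp: {mean: 0.894, ci: [0.886, 0.902]}}
    - {ages: [40, 50], se: {mean: 0.70, ci: [0.61, 0.80]}, sp: {mean: 0.867, ci: [0.863, 0.872]}}
    - {ages: [50, 60], se: {mean: 0.81, ci: [0.73, 0.89]}, sp: {mean: 0.873, ci: [0.868, 0.879]}}
    - {ages: [60, 70], se: {mean: 0.84, ci: [0.77, 0.91]}, sp: {mean: 0.890, ci: [0.884, 0.895]}}

stages:
  # Stage-at-diagnosis rows (in_situ, local, regional, distant). Printed rows
  # may sum to 101% from rounding; they are renormalized proportionally.
  mri_detected:
    p: [0.16, 0.68, 0.16, 0.01]
    ci:
      in_situ: [0.10, 0.22]
      local: [0.62, 0.72]
      regional: [0.10, 0.22]
      distant: [0.00, 0.04]
  mam_detected:
    p: [0.27, 0.49, 0.22, 0.02]
    ci:
      in_situ: [0.17, 0.38]
      local: [0.38, 0.58]
      regional: [0.12, 0.31]
      distant: [0.00, 0.11]
  non_screen:
    p: [0.05, 0.48, 0.40, 0.08]
    ci:
      in_situ: [0.03, 0.06]
      local: [0.46, 0.50]
      regional: [0.37, 0.42]
      distant: [0.06, 0.09]

costs:
  mri_screen: {mean: 277, ci: [196, 376]}
  mammogram: {mean: 95, ci: [55, 146]}
  workup: {mean: 187, ci: [106, 292]}
  treatment:
    # Totals over the first 18 months after diagnosis; allocated to the three
    # 6-month treatment cycles in equal thirds.
    in_situ: {mean: 3427, ci: [1713, 5140]}
    local: {mean: 10940, ci: [1997, 27335]}
    regional: {mean: 23612, ci: [5075, 56124]}
    distant: {mean: 15645, ci: [4171, 34561]}
  end_of_life: {mean: 26704, ci: [11851, 47489]}

utilities:
  workup: {mean: 0.987, ci: [0.761, 1.0]}
  workup_duration_days: 14
  treatment:
    in_situ: {mean: 0.965, ci: [0.463, 1.0]}
    local: {mean: 0.860, ci: [0.330, 1.0]}
    regional: {mean: 0.675, ci: [0.315, 0.929]}
    distant: {mean: 0.380, ci: [0.211, 0.564]}
  progression: {mean: 0.380, ci: [0.211, 0.564]}
  remission: {mean: 0.965, ci: [0.463, 1.0]}

survival:
  # Interval survival anchors (5-year, 10-year) by stage at diagnosis; each
  # stage is calibrated to a two-parameter Weibull. In-situ disease carries no
  # excess mortality (degenerate spec).
  in_situ: null
  local:
    s5: {mean: 0.968, ci: [0.964, 0.971]}
    s10: {mean: 0.906, ci: [0.892, 0.917]}
  regional:
    s5: {mean: 0.888, ci: [0.847, 0.916]}
    s10: {mean: 0.712, ci: [0.631, 0.769]}
  distant:
    s5: {mean: 0.261, ci: [0.219, 0.299]}
    s10: {mean: 0.102, ci: [0.072, 0.132]}

psa:
  n_draws: 10000
  wtp_grid: [0, 10000, 20000, 30000, 40000, 50000, 60000, 70000, 80000,
             90000, 100000, 120000, 140000, 160000, 180000, 200000]

validation_targets:
  # Reference values for `brcascreen validate`: model outputs at mean
  # parameters are checked against these published figures.
  cumulative_incidence_by_65: {value: 42.7, tol: 1.5}
  program_sensitivity_combined: {value: 93.9, tol: 2.0}
  program_sensitivity_mammography: {value: 71.7, tol: 2.0}
  survival_to_65_combined: {value: 80.1, tol: 1.5}
  survival_to_65_mammography: {value: 79.1, tol: 1.5}
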