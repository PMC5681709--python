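# Model inputs for the China tobacco-control ECEA (male population, 2015 US$).
# Every number is a published model input; see docs/methods.md for provenance notes.

population:
  age_groups:
    - {label: "0-4",   males: 46223844}
    - {label: "5-9",   males: 42116819}
    - {label: "10-14", males: 44333255}
    - {label: "15-19", males: 57372413}
    - {label: "20-24", males: 69787588}
    - {label: "25-29", males: 54148396}
    - {label: "30-34", males: 48300078}
    - {label: "35-39", males: 60477911}
    - {label: "40-44", males: 62353282}
    - {label: "45-49", males: 52513698}
    - {label: "50-54", males: 41888301}
    - {label: "55-59", males: 41743573}
    - {label: "60-64", males: 28223579}
    - {label: "65-69", males: 19966448}
    - {label: "70-74", males: 15697892}
    - {label: "75-79", males: 10754066}
    - {label: "80-84", males: 5524515}
    - {label: "85+",   males: 2757397}

smoking:
  prevalence:
    "15-19": 0.140
    "20-24": 0.488
    "25-29": 0.530
    "30-34": 0.522
    "35-39": 0.575
    "40-44": 0.680
    "45-49": 0.667
    "50-54": 0.580
    "55-59": 0.577
    "60-64": 0.473
    "65-69": 0.376
    "70-74": 0.210
    "75-79": 0.190
    "80-84": 0.170
    "85+":   0.130
  # boys under 15 are assumed to initiate at the 15-19 year-old prevalence
  future_initiation_prevalence: 0.140
  quintile_prevalence_multipliers: [1.14, 1.14, 1.14, 1.14, 0.86]
  renormalize_multipliers: false
  cigarettes_per_day: [15.6, 15.5, 13.8, 12.7, 12.7]

elasticity:
  adult:  [-0.64, -0.51, -0.38, -0.25, -0.12]
  youth:  [-1.28, -1.02, -0.76, -0.50, -0.24]
  future: [-1.28, -1.02, -0.76, -0.50, -0.24]
  participation_share: 0.5

prices:
  price_before: 2.00
  price_after: 3.50
  tax_share_before: 0.56
  tax_share_after: 0.75
  pack_size: 20

workplace_ban:
  relative_prevalence_reduction: 0.09
  absolute_mode:
    absolute_reduction_raw: 0.038
    worksite_coverage: 0.31
    employed_fraction: 0.82
    absolute_reduction_adjusted: 0.022
    consumption_drop: 3.1
    age_cap: 60

mortality:
  attributable_fraction: 0.50
  risk_reduction_by_age:
    "15-19": 0.969
    "20-24": 0.948
    "25-29": 0.921
    "30-34": 0.892
    "35-39": 0.866
    "40-44": 0.837
    "45-49": 0.795
    "50-54": 0.729
    "55-59": 0.628
    "60-64": 0.499
    "65-69": 0.364
    "70-74": 0.247
    "75-79": 0.157
    "80-84": 0.091
    "85+":   0.045
  cause_shares:
    copd: 0.113
    stroke: 0.455
    heart: 0.228
    neoplasm: 0.204

costs:
  treatment_cost:
    copd: 2256
    stroke: 2197
    heart: 11774
    neoplasm: 14794
  utilization:
    copd: 0.33
    stroke: 0.80
    heart: 0.81
    neoplasm: 0.50
  quintile_utilization_multipliers: [0.79, 0.98, 1.00, 1.08, 1.15]
  reimbursement_fraction: 0.48

income:
  mean_income: 3039
  gini: 0.43
  quintile_bounds: [992, 1870, 2973, 4718]
  poverty_line_per_day: 1.90
  catastrophic_share: 0.10

analysis:
  # "residual": total cigarette demand falls by the full elasticity; quitting carries
  # half and continuing smokers' intensity carries the remainder.
  # "independent": intensity falls by |eps| * (1 - participation_share) * dp/p on its own.
  consumption_response: residual
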