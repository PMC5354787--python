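# Model parameter registry: base-case values, one-way ranges, and PSA
# distributions for the first-line EGFR-mutant advanced-NSCLC
# cost-effectiveness model (Chinese health-care setting, 2015 US$).
#
# Conventions:
#   - gamma distributions are (shape, scale); normal are (mean, sd);
#     beta are (alpha, beta).
#   - entries with identical low/high are structural constants that are
#     not varied in one-way sensitivity analysis.
#   - entries without `dist` are held fixed in probabilistic sensitivity
#     analysis.
#   - where the literature reports no range, low/high default to +/-25%
#     of the base-case value.
parameters:
  - name: weibull_scale
    base: 0.1029
    low: 0.1029
    high: 0.1029
    kind: scalar
    units: per cycle^shape
    source: survival-fit
  - name: weibull_shape
    base: 1.3077
    low: 1.3077
    high: 1.3077
    kind: scalar
    units: dimensionless
    source: survival-fit
  - name: hr_maintenance
    base: 0.59
    low: 0.4425
    high: 0.7375
    dist: {family: normal, p1: 0.59, p2: 0.161}
    kind: hazard_ratio
    units: hazard ratio vs control
    source: evidence-synthesis
  - name: hr_gefitinib
    base: 0.48
    low: 0.29
    high: 0.80
    dist: {family: normal, p1: 0.48, p2: 0.13}
    kind: hazard_ratio
    units: hazard ratio vs control
    source: evidence-synthesis
  - name: hr_icotinib
    base: 0.40
    low: 0.19
    high: 0.81
    dist: {family: normal, p1: 0.40, p2: 0.158}
    kind: hazard_ratio
    units: hazard ratio vs control
    source: evidence-synthesis
  - name: prob_death_post_progression
    base: 0.086
    low: 0.08
    high: 0.093
    dist: {family: beta, p1: 751.1, p2: 7982.7}
    kind: probability
    units: per 21-day cycle
    source: literature
  - name: egfr_prevalence
    base: 0.47
    low: 0.20
    high: 0.76
    dist: {family: normal, p1: 0.47, p2: 0.143}
    kind: probability
    units: proportion
    source: literature
  - name: prob_sae_control
    base: 0.456
    low: 0.342
    high: 0.57
    dist: {family: beta, p1: 33.6, p2: 40.1}
    kind: probability
    units: cumulative probability
    source: literature
  - name: prob_sae_maintenance
    base: 0.637
    low: 0.478
    high: 0.796
    dist: {family: beta, p1: 22.4, p2: 12.8}
    kind: probability
    units: cumulative probability
    source: literature
  - name: prob_sae_gefitinib
    base: 0.10
    low: 0.075
    high: 0.125
    dist: {family: beta, p1: 53.3, p2: 479.3}
    kind: probability
    units: cumulative probability
    source: literature
  - name: prob_sae_icotinib
    base: 0.07
    low: 0.053
    high: 0.088
    dist: {family: beta, p1: 56.3, p2: 747.4}
    kind: probability
    units: cumulative probability
    source: literature
  - name: body_surface_area
    base: 1.72
    low: 1.5
    high: 1.9
    dist: {family: normal, p1: 1.72, p2: 0.102}
    kind: scalar
    units: m^2
    source: literature
  - name: cost_pemetrexed_500mg
    base: 967.57
    low: 533.02
    high: 2126.51
    dist: {family: gamma, p1: 2303.0, p2: 0.42}
    kind: cost
    units: USD per 500 mg vial
    source: literature
  - name: cost_chemo_backbone_per_cycle
    base: 518.4
    low: 388.8
    high: 648.0
    dist: {family: gamma, p1: 4064.3, p2: 0.13}
    kind: cost
    units: USD per 21-day cycle (cisplatin + administration)
    source: literature
  - name: cost_icotinib_per_day
    base: 31.72
    low: 15.86
    high: 31.72
    dist: {family: gamma, p1: 248.7, p2: 0.13}
    kind: cost
    units: USD per day
    source: local-charge
  - name: cost_gefitinib_per_day
    base: 37.43
    low: 18.71
    high: 37.43
    dist: {family: gamma, p1: 293.4, p2: 0.13}
    kind: cost
    units: USD per day
    source: local-charge
  - name: cost_followup_per_unit
    base: 55.6
    low: 41.7
    high: 69.4
    dist: {family: gamma, p1: 437.5, p2: 0.13}
    kind: cost
    units: USD per follow-up unit
    source: literature
  - name: cost_salvage_per_cycle
    base: 2352.7
    low: 1921.1
    high: 4383.3
    dist: {family: gamma, p1: 8812.4, p2: 0.27}
    kind: cost
    units: USD per 21-day cycle
    source: literature
  - name: cost_terminal_care
    base: 2042.91
    low: 793.65
    high: 5456.19
    dist: {family: gamma, p1: 3508.8, p2: 0.58}
    kind: cost
    units: USD one-off at death
    source: literature
  - name: cost_supportive_per_cycle
    base: 337.5
    low: 158.7
    high: 793.7
    dist: {family: gamma, p1: 703.2, p2: 0.48}
    kind: cost
    units: USD per 21-day cycle
    source: literature
  - name: cost_sae_unit
    base: 507.4
    low: 189.7
    high: 825.0
    dist: {family: gamma, p1: 1588.6, p2: 0.32}
    kind: cost
    units: USD per cycle (control-strategy SAE management)
    source: literature
  - name: cost_egfr_test
    base: 380.95
    low: 158.73
    high: 476.19
    dist: {family: gamma, p1: 1792.0, p2: 0.21}
    kind: cost
    units: USD per test
    source: local-charge
  - name: utility_pfs
    base: 0.82
    low: 0.78
    high: 0.86
    dist: {family: beta, p1: 373.6, p2: 82.0}
    kind: utility
    units: utility weight
    source: literature
  - name: utility_pps
    base: 0.58
    low: 0.50
    high: 0.66
    dist: {family: beta, p1: 84.0, p2: 60.9}
    kind: utility
    units: utility weight
    source: literature
  - name: disutility_sae
    base: 0.35
    low: 0.31
    high: 0.39
    dist: {family: beta, p1: 199.1, p2: 369.7}
    kind: utility
    units: utility decrement
    source: literature
  - name: salvage_uptake
    base: 0.566
    low: 0.26
    high: 0.72
    kind: probability
    units: proportion receiving salvage chemotherapy
    source: literature
  - name: discount_rate_annual
    base: 0.05
    low: 0.05
    high: 0.05
    kind: scalar
    units: per year
    source: guideline
  - name: wtp_threshold
    base: 22200.0
    low: 22200.0
    high: 22200.0
    kind: cost
    units: USD per QALY (3x 2015 Chinese per-capita GDP)
    source: guideline
  - name: pap_cap_gefitinib
    base: 11538.0
    low: 11538.0
    high: 11538.0
    kind: cost
    units: USD per patient (assistance-program copay cap)
    source: local-charge
  - name: pap_cap_icotinib
    base: 11077.0
    low: 11077.0
    high: 11077.0
    kind: cost
    units: USD per patient (assistance-program copay cap)
    source: local-charge
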