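# Synthetic demo device profiles.
#
# These presets are ILLUSTRATIVE ONLY: they are hand-shaped so that each
# model's simulated behaviour is qualitatively similar to published
# descriptions of commercial meters (sign of bias, hematocrit sensitivity,
# reduced precision at low glucose, error rates, reporting unit, cost tier).
# They are NOT measured device parameters and must not be quoted as such.
#
# Fields: base_bias_pct (proportional bias at 40% Hct), hct_coeff_pct_per_hct
# (extra % bias per Hct point above 40%), sigma_low/high_pct (relative noise
# SD at 40 / 150 mg/dL), error_rate (per-measurement instrument-error
# probability), reads_mmol, display_floor (mg/dL), cost_tier.
profiles:
  - device_model: StatStrip
    base_bias_pct: -2.0
    hct_coeff_pct_per_hct: 0.10
    sigma_low_pct: 6.0
    sigma_high_pct: 3.0
    cost_tier: exceeds_2_3x
  - device_model: StatStrip Xpress 2
    base_bias_pct: -1.5
    hct_coeff_pct_per_hct: 0.10
    sigma_low_pct: 6.0
    sigma_high_pct: 3.0
    cost_tier: exceeds_2_3x
  - device_model: Accu-Chek Guide
    base_bias_pct: 2.0
    sigma_low_pct: 3.5
    sigma_high_pct: 2.5
  - device_model: Accu-Chek GuideMe
    base_bias_pct: -2.0
    sigma_low_pct: 3.5
    sigma_high_pct: 2.5
  - device_model: Accu-Chek Instant
    base_bias_pct: -4.0
    hct_coeff_pct_per_hct: -0.05
    sigma_low_pct: 3.0
    sigma_high_pct: 2.5
    reads_mmol: true
    cost_tier: meets_TPP
  - device_model: Accu-Chek Performa
    base_bias_pct: -5.0
    sigma_low_pct: 3.0
    sigma_high_pct: 3.0
  - device_model: Accu-Chek Active
    base_bias_pct: -6.0
    hct_coeff_pct_per_hct: -0.30
    sigma_low_pct: 8.0
    sigma_high_pct: 6.0
    cost_tier: meets_TPP
  - device_model: GlucoNavii
    base_bias_pct: -7.0
    hct_coeff_pct_per_hct: -0.25
    sigma_low_pct: 9.0
    sigma_high_pct: 7.0
  - device_model: OneTouchUltra 2
    base_bias_pct: 2.0
    hct_coeff_pct_per_hct: -0.50
    sigma_low_pct: 16.0
    sigma_high_pct: 9.0
  - device_model: Nipro Premier
    base_bias_pct: 1.0
    sigma_low_pct: 20.0
    sigma_high_pct: 4.0
    error_rate: 0.036
    reads_mmol: true
    display_floor: 20.0
  - device_model: HemoCue Glucose 201 RT
    base_bias_pct: -2.0
    hct_coeff_pct_per_hct: -1.00
    sigma_low_pct: 18.0
    sigma_high_pct: 4.0
    error_rate: 0.033
    cost_tier: exceeds_2_3x
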