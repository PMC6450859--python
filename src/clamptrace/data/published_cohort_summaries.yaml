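# Group-level summary statistics printed by the published two-group clamp
# study that this package models (black West African men, BAM, vs white
# European men, WEM, with early type 2 diabetes). Raw subject-level data
# were never deposited, so these printed summaries are the only reference
# inputs available: the simulator calibrates to them and the worked-example
# arithmetic recomputes the printed contrasts from them.
#
# mean_sd entries: [n_bam, mean_bam, sd_bam, n_wem, mean_wem, sd_wem]
# geometric entries: geometric mean with 95% CI per group.

anthropometry:
  weight_kg: {n: [18, 15], mean: [90.9, 94.2], sd: [9.3, 11.6]}
  height_cm: {n: [18, 15], mean: [175.6, 176.8], sd: [7.6, 5.8]}
  bsa_m2: {n: [18, 15], mean: [2.08, 2.13], sd: [0.14, 0.15]}
  vat_kg: {n: [17, 14], mean: [3.72, 5.68], sd: [1.07, 2.43]}
  sat_kg: {n: [16, 14], mean: [11.8, 11.8], sd: [3.9, 2.6]}
  muscle_kg: {n: [17, 14], mean: [20.7, 18.5], sd: [2.5, 3.0]}

basal:
  glucose_mmol_l: {n: [18, 15], mean: [5.89, 5.71], sd: [0.39, 0.63]}
  insulin_pmol_l_gm: {n: [18, 15], gm: [45.7, 57.3], ci_low: [36.8, 39.5], ci_high: [56.7, 83.2]}
  nefa_mmol_l: {n: [18, 15], mean: [0.48, 0.55], sd: [0.17, 0.18]}

turnover:
  m_value_mg_kg_min:
    n: [18, 15]
    mean: [4.52, 4.00]
    sd: [2.07, 1.70]
    printed_difference: 0.52
    printed_ci: [-0.82, 1.89]
  rd_umol_kg_min:
    n: [18, 15]
    mean: [26.8, 24.2]
    sd: [10.4, 8.5]
    printed_difference: 2.60
    printed_ci: [-4.22, 9.41]
  basal_ra_umol_kg_min:
    n: [15, 12]
    mean: [8.82, 9.25]
    sd: [1.49, 1.66]
    printed_difference: -0.43
    printed_ci: [-1.69, 0.81]
  clamp_ra_umol_kg_min:
    n: [18, 15]
    mean: [5.76, 6.50]
    sd: [1.73, 2.34]
    printed_difference: -0.74
    printed_ci: [-2.18, 0.71]
  basal_glycerol_ra_umol_kg_min_gm:
    n: [15, 12]
    gm: [1.51, 1.82]
    ci_low: [1.31, 1.55]
    ci_high: [1.75, 2.15]
    printed_ratio: 0.83
    printed_ratio_ci: [0.67, 1.02]
  clamp_glycerol_ra_umol_kg_min:
    n: [18, 13]
    mean: [1.06, 1.18]
    sd: [0.47, 0.33]
    printed_difference: -0.12
    printed_ci: [-0.43, 0.19]

sensitivity_percent:
  pct_increase_rd: {n: [15, 12], mean: [203.5, 166.3], sd: [126.2, 102.5]}
  pct_supp_egp: {n: [15, 12], mean: [-36.4, -34.8], sd: [19.7, 20.7]}
  pct_supp_glycerol: {n: [15, 10], mean: [-37.2, -37.5], sd: [16.0, 13.7]}

other:
  m_over_i: {n: [18, 15], mean: [0.030, 0.026], sd: [0.017, 0.011]}
  muscle_adipose_correlation_r: [0.25, 0.78]
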