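# Two-stage hyperinsulinaemic-euglycaemic clamp protocol defaults.
# Tracers start at t = -120 min; insulin stages at 0 and 120 min.
glucose_tracer_prime_mg_kg: 2.0
glucose_tracer_rate_mg_kg_min: 0.02
glycerol_tracer_prime_mg_kg: 0.12
glycerol_tracer_rate_mg_kg_min: 0.0067
insulin_rate_low_mU_m2_min: 10.0
insulin_rate_high_mU_m2_min: 40.0
infusate_enrichment_low_mg_g: 8.0
infusate_enrichment_high_mg_g: 10.0
v_frac: 0.22
glycaemic_target_mmol_l: 5.0
basal_start_min: -120.0
stage1_start_min: 0.0
stage2_start_min: 120.0
clamp_end_min: 240.0
basal_window: [-30.0, 0.0]
low_window: [90.0, 120.0]
high_window: [210.0, 240.0]
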