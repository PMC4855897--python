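n_residents = 8
n_dispersers = 6
n_exploratory = 2
n_migrants = 6
true_betas = [0.155, -0.135, 0.288, 0.113, -0.113, -0.053]
fix_interval_min = 120.0
fix_success_prob = {"lotek" = 0.817, "argos" = 0.662}
outlier_prob = 0.01
outlier_offset_km = [10.0, 40.0]
dispersal_displacement_km = [29.16, 98.01]
dispersal_duration_days = [12.0, 47.0]
start_date = "2009-03-25"
n_days = 228
route_steer_ndvi = 0.0
n_candidates = 50
rng_seed = 3
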