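# Lithuanian Red old genotype — herd calibration.
# Units: ECM in kg per 305-d lactation; rates as fractions [0,1];
# incidences as cases per 100 cow-years; stillbirth as % of calvings.
# stillbirth_rate is deliberately omitted (not recorded for this breed);
# the loader falls back to the LR value with a warning.
breed: LROG
herd_size_target: 200
production:
  ecm_305d:
    "1": 4916
    "2": 5553
    "3+": 5949
  fat_pct: 4.56
  protein_pct: 3.48
reproduction:
  calving_interval_days: 421
  age_first_calving_months: 24.6
  heat_obs_rate_cows: 0.4524
  heat_obs_rate_heifers: 0.5556
  conception_rate_cows: 0.50      # simulated input, not recorded
  conception_rate_heifers: 0.625
  start_breeding_days: 45.62
incidence_per_100cy:
  milk_fever: 3.5
  dystocia: 1.3
  metritis: 7.0
  ketosis: 4.4
  mastitis: 26
  lameness: 19
mortality:
  early_calf: 3.5
  late_calf: 2.0
  cow: 5.0
cow_live_weight_kg: 550
feed_model:
  maintenance_sfu_per_day: 5.0
  sfu_per_kg_ecm: 0.43
  concentrate_share: 0.25   # lower concentrate use at the lower yield
  heifer_sfu_per_day: 5.0
  heifer_concentrate_share: 0.20
  calf_milk_powder_kg_per_day: 0.6
  milk_feeding_weeks: 8
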