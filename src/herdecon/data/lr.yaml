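# Lithuanian Red (open population) — herd calibration.
# Units: ECM in kg per 305-d lactation; rates as fractions [0,1];
# incidences as cases per 100 cow-years; stillbirth as % of calvings.
breed: LR
herd_size_target: 200
production:
  ecm_305d:
    "1": 6907
    "2": 7596
    "3+": 7469
  fat_pct: 4.43
  protein_pct: 3.50
reproduction:
  calving_interval_days: 412
  age_first_calving_months: 25.8
  heat_obs_rate_cows: 0.4516
  heat_obs_rate_heifers: 0.5508
  conception_rate_cows: 0.45      # = (1 / 2.2 inseminations) x 100, rounded
  conception_rate_heifers: 0.5882
  start_breeding_days: 46.67
incidence_per_100cy:
  milk_fever: 3.5
  dystocia: 1.3
  metritis: 7.0
  ketosis: 4.4
  mastitis: 26
  lameness: 19
stillbirth_rate: 5.2
mortality:
  early_calf: 3.5
  late_calf: 2.0
  cow: 5.0
cow_live_weight_kg: 550
feed_model:
  maintenance_sfu_per_day: 5.0
  sfu_per_kg_ecm: 0.43
  concentrate_share: 0.35
  heifer_sfu_per_day: 5.0
  heifer_concentrate_share: 0.20
  calf_milk_powder_kg_per_day: 0.6
  milk_feeding_weeks: 8
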