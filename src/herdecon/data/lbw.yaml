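# Lithuanian Black-and-White (open population) — herd calibration.
# Units: ECM in kg per 305-d lactation; rates as fractions [0,1];
# incidences as cases per 100 cow-years; stillbirth as % of calvings.
breed: LBW
herd_size_target: 200
production:
  ecm_305d:
    "1": 6741
    "2": 7648
    "3+": 7526
  fat_pct: 4.31
  protein_pct: 3.35
reproduction:
  calving_interval_days: 424
  age_first_calving_months: 27.2
  heat_obs_rate_cows: 0.4316
  heat_obs_rate_heifers: 0.5991
  conception_rate_cows: 0.50      # = (1 / 2.0 inseminations) x 100
  conception_rate_heifers: 0.625
  start_breeding_days: 44.27
incidence_per_100cy:
  milk_fever: 3.5
  dystocia: 1.3
  metritis: 8.0
  ketosis: 4.4
  mastitis: 26
  lameness: 19
stillbirth_rate: 6.5
# Not part of the recorded calibration; model assumptions (% per year /
# % per rearing window).
mortality:
  early_calf: 3.5   # dying 3-14 d postpartum
  late_calf: 2.0    # dying 189-458 d postpartum
  cow: 5.0          # per cow-year, causes unrelated to modelled diseases
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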