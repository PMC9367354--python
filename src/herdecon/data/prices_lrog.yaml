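# Price/cost book (EUR), LROG. Heifer, bull-calf and semen prices are
# breed-specific; everything else is shared across breeds.
milk_price_per_kg_ecm: 0.29
slaughter_price_per_kg_live: 0.94
dead_cow_disposal: 33
dead_heifer_disposal: 21
dead_calf_disposal: 9
pregnant_heifer_price: 1050
open_heifer_price: 550
bull_calf_price: 150
milk_powder_per_kg: 2.02
heifer_concentrate_per_sfu: 0.23
heifer_roughage_per_sfu: 0.10
treatment_cost:
  mastitis: 89
  milk_fever: 54
  dystocia: 69
  metritis: 72
  ketosis: 70
semen_cost: 7
# Calibration constants (not in the published book): cow ration split
# and residual "other" cost lines.
cow_concentrate_per_sfu: 0.40
cow_roughage_per_sfu: 0.12
other_costs_per_cow_year: 202
other_costs_per_heifer_year: 50
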