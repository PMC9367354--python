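# herdecon

Stochastic bio-economic dairy-herd simulation and derivation of
economic values (EVs) for breeding-goal traits.

The pipeline mirrors the classic bio-economic EV design:

1. **Herd simulation** (`herdecon.simulator`) — a mechanistic, dynamic,
   stochastic herd model in weekly steps (lactation curves, oestrus /
   insemination / conception, gestation and calving with dystocia and
   stillbirth, disease episodes from annual incidences, mortality,
   culling, heifer rearing and replacement), producing annual technical
   results per Monte-Carlo replicate. The engine is vectorized over
   replicates and uses a fixed random-draw layout so paired runs share
   randomness (common random numbers with monotone coupling).
2. **Economics** (`herdecon.economics`) — converts technical results
   into a five-line income / seven-line cost statement per cow-year and
   the contribution margin (total income − variable costs).
3. **Scenario engine** (`herdecon.scenarios`) — paired "low"/"high"
   scenarios per trait (±1 percentage point for rate traits, ±250 kg of
   305-d ECM for milk), simulated with common random numbers.
4. **EV regression** (`herdecon.regression`) — OLS of net return on the
   nominal trait level, trait-specific mediator variables (to avoid
   double counting across correlated breeding-goal traits) and the
   within-scenario realized deviation. The coefficient on the trait is
   the EV; 100 × |EV| is the cost per case for disease traits.

Breed calibrations (LBW, LR, LROG: production, reproduction, disease
incidence) and the EUR price book ship as YAML under
`src/herdecon/data/` and are the canonical inputs
(`herdecon.config_io`).

## CLI

```sh
# simulate a herd and write annual technical + economic CSVs
herdecon simulate --breed-config src/herdecon/data/lbw.yaml \
    --price-config src/herdecon/data/prices_lbw.yaml \
    --years 40 --burn-in 10 --reps 100 --seed 1 --out out/sim

# derive the EV of one trait (paired scenarios + mediator regression)
herdecon derive-ev --breed-config src/herdecon/data/lbw.yaml \
    --price-config src/herdecon/data/prices_lbw.yaml \
    --trait mastitis --fast --seed 1 --out out/ev

# collect per-trait EV files into a traits x breeds summary
herdecon report --in-dir out/ev --out out/summary.csv
```

Traits: `ecm mastitis lameness ketosis milk_fever metritis dystocia
stillbirth early_calf_mortality late_calf_mortality cow_mortality
cr_cows cr_heifers ho_cows ho_heifers`. Every run writes a
`manifest.json` (config checksums, seed, options, version) for
reproducibility; `--fast` runs a scaled-down design (100 replicates,
12 years) and flags the outputs accordingly.

## Notes on calibration

Values that no herd-recording scheme publishes (per-disease effect
magnitudes, feed model, cow ration price split, residual "other" cost
lines, base cow/calf mortality) are documented model assumptions in the
config schema — the loader logs a WARN when they are defaulted, and all
of them can be overridden per breed file. The oestrus-detection scale
and heifer breeding start are solved at run time so that realized
calving intervals and ages at first calving match the calibrated
values; the scenario engine freezes them before perturbing so fertility
scenarios keep their causal effect.
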