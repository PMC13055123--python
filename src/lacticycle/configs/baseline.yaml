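# Baseline scenario: 10,000 MTA cultivated-meat facility, 3 g/L lactic acid.
# Omitted fields are filled from the package defaults (and flagged as such in
# the loaded bundle's provenance).
facility:
  cm_annual_production: 1.0e7      # kg CM / yr
  operating_hours: 8000.0          # h / yr
  media_per_batch: 144382.0        # L
  batch_mass: 3080.0               # kg CM  -> 46.9 L media per kg CM
  water_reuse_fraction: 0.75
  cm_price: 20.0                   # $/kg CM
  cm_baseline_gwp: 14.2            # kg CO2eq / kg CM, no recovery
  cm_baseline_ced: 278.0           # MJ / kg CM, no recovery
spent_media:
  lactic_acid_conc: 3.0            # g/L
  glucose_conc: 1.8                # g/L
process:
  mf_concentration_factor: 15.0
  ac_regen_bed_volumes: 5.0
  iex_resin_capacity: 2.0          # eq/L
  iex_regen_bed_volumes: 3.0
  iex_regen_acid_molarity: 1.0     # mol/L H2SO4
  nf_stages: 3
  nf_stage_retention: 0.95
  nf_target_conc: 77.0             # g/L
  mee_steam_economy: 4.5
  mee_effects: 5
  product_mass_fraction: 0.88
costs:
  la_price: 1.41                   # $/kg contained lactic acid
  depreciation_years: 15.0
  membrane_lifetime_years: 5.0
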