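# Reproduction run: published prevalences, pooled RRs and the
# synthetic reverse-engineered baseline-DALY validation fixture.
# Witnessing-family-violence rows exist in the effects table but are
# excluded here (too few consequence studies to include in totals).
prevalence_path: prevalence_optimus.csv
effects_path: study_rr_table.csv
baseline_path: baseline_dalys_synthetic.csv
life_table_path: life_table_yll.csv
homicide_path: homicides_2009.csv
welfare_path: welfare_spend_2015.csv
econ:
  gdp_per_capita: 73061.19510059859
  median_monthly_earnings_base: 3120
  cpi_ratio: 1.0455128205128206
  labour_force: 21084500
  gdp_total: 4000000000000.0
  exchange_rate: 12.81
include_exposures:
- sexual
- physical
- emotional
- neglect
wage_reductions:
  physical: 0.117
  emotional: 0.092
cause_exclusions: {}
envelope_map:
  smi:
  - anxiety
  - depression
pooling_scale: log
homicide_reference_year: 2009
seed: 0
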