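# Economy-level scalars for the 2015 costing year (ZAR).
# gdp_per_capita is implied by the published burden table
# (166,409 million / 2,277,666 DALYs); the fatal-burden section
# implies ~73,557 (6.2 bn / 84,287) -- an alternative if preferred.
# gdp_total back-computed from annual earnings loss 25.2 bn = 0.63% of GDP.
# exchange_rate (ZAR/USD) is indicative only, not authoritative.
gdp_per_capita: 73061.19510059859
median_monthly_earnings_base: 3120
cpi_ratio: 1.0455128205128206
labour_force: 21084500
gdp_total: 4000000000000.0
exchange_rate: 12.81
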