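# Reference nurse regimen: 12-h ward shifts every third day during a
# three-month duty block (30 shifts/yr).
profession: nurse
sex: female
gas_concentration: 170.0      # Bq/m^3
aerosol_concentration: 18.0   # Bq/m^3
hours_per_intake: 12.0
intakes_per_year: 30
intake_spacing: 3.0           # d
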