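# Reference technician regimen: weekly radioiodine preparation/administration
# in the hot room (6-h average work period, Friday deliveries, 50/yr).
profession: technician
sex: male
gas_concentration: 490.0      # Bq/m^3
aerosol_concentration: 7.0    # Bq/m^3
hours_per_intake: 6.0
intakes_per_year: 50
intake_spacing: 7.0           # d
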