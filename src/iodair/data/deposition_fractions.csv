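region,sex,form,fraction,provenance
ET1,male,aerosol_5um,2.80e-1,HRTM 5 um AMAD sitting adult male
ET2,male,aerosol_5um,3.40e-1,HRTM 5 um AMAD sitting adult male
BB_fast_seq,male,aerosol_5um,1.20e-2,HRTM 5 um AMAD sitting adult male
BB_slow,male,aerosol_5um,4.30e-3,HRTM 5 um AMAD sitting adult male
bb_fast_seq,male,aerosol_5um,1.50e-2,HRTM 5 um AMAD sitting adult male
bb_slow,male,aerosol_5um,8.70e-3,HRTM 5 um AMAD sitting adult male
AI,male,aerosol_5um,1.00e-1,HRTM 5 um AMAD sitting adult male
ET1,female,aerosol_5um,2.70e-1,HRTM 5 um AMAD sitting adult female
ET2,female,aerosol_5um,3.30e-1,HRTM 5 um AMAD sitting adult female
BB_fast_seq,female,aerosol_5um,1.10e-2,HRTM 5 um AMAD sitting adult female
BB_slow,female,aerosol_5um,3.90e-3,HRTM 5 um AMAD sitting adult female
bb_fast_seq,female,aerosol_5um,1.80e-2,HRTM 5 um AMAD sitting adult female
bb_slow,female,aerosol_5um,1.00e-2,HRTM 5 um AMAD sitting adult female
AI,female,aerosol_5um,9.40e-2,HRTM 5 um AMAD sitting adult female
ET1,male,gas,1.00e-1,elemental iodine vapour; 100% total respiratory deposition
ET2,male,gas,4.00e-1,elemental iodine vapour
BB_fast_seq,male,gas,5.00e-1,elemental iodine vapour; bronchial deposit assigned to fast-clearing BB
BB_slow,male,gas,0.0,vapour does not populate slow bronchial compartment
bb_fast_seq,male,gas,0.0,vapour does not reach bronchioles
bb_slow,male,gas,0.0,vapour does not reach bronchioles
AI,male,gas,0.0,vapour does not reach alveolar-interstitial region
ET1,female,gas,1.00e-1,vapour deposition sex-independent
ET2,female,gas,4.00e-1,vapour deposition sex-independent
BB_fast_seq,female,gas,5.00e-1,vapour deposition sex-independent
BB_slow,female,gas,0.0,vapour does not populate slow bronchial compartment
bb_fast_seq,female,gas,0.0,vapour does not reach bronchioles
bb_slow,female,gas,0.0,vapour does not reach bronchioles
AI,female,gas,0.0,vapour does not reach alveolar-interstitial region
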