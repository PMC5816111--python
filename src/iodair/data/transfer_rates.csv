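from_compartment,to_compartment,rate_per_day,form,provenance
ET1,environment,1.0,both,HRTM extrinsic clearance of anterior nose (nose blowing)
AI,bb_fast,0.02,aerosol_5um,HRTM particle transport; single AI compartment at the dominant slow rate
bb_fast,BB_fast,2.0,aerosol_5um,HRTM particle transport bb1 -> BB1
bb_slow,BB_fast,0.03,aerosol_5um,HRTM particle transport bb2 -> BB1
BB_fast,ET2,10.0,aerosol_5um,HRTM particle transport BB1 -> ET2
BB_slow,ET2,0.03,aerosol_5um,HRTM particle transport BB2 -> ET2
ET2,stomach,100.0,aerosol_5um,HRTM particle transport ET2 swallowed to stomach
ET2,blood,100.0,both,Type F fast dissolution (10 min half-time); vapour absorbed at same rate
BB_fast,blood,100.0,both,Type F fast dissolution / vapour absorption
BB_slow,blood,100.0,both,Type F fast dissolution
bb_fast,blood,100.0,both,Type F fast dissolution
bb_slow,blood,100.0,both,Type F fast dissolution
AI,blood,100.0,both,Type F fast dissolution
stomach,small_intestine,24.0,both,GI transit: stomach emptying 1 h mean residence
small_intestine,blood,6.0,both,GI transit: SI 4 h mean residence; iodide fully absorbed (f1 = 1)
colon,faeces,1.0,both,GI transit: colon clearance to faeces
blood,thyroid,0.83178,both,iodide recycling model: 30% thyroid uptake of 2.7726/d blood clearance (T1/2 0.25 d)
blood,bladder,1.94082,both,iodide recycling model: 70% of blood iodide to urinary excretion
bladder,urine,12.0,both,urinary bladder voiding (2 h mean residence)
thyroid,organic,0.00866434,both,thyroidal organic iodine secretion T1/2 80 d
organic,blood,0.05198604,both,extrathyroidal organic iodine T1/2 12 d; 90% deiodinated back to blood iodide
organic,colon,0.00577623,both,extrathyroidal organic iodine T1/2 12 d; 10% excreted in faeces
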