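tissue,w_t,provenance
red_marrow,0.12,ICRP 103 tissue weighting factor
colon,0.12,ICRP 103 tissue weighting factor
lung,0.12,ICRP 103 tissue weighting factor
stomach,0.12,ICRP 103 tissue weighting factor
breast,0.12,ICRP 103 tissue weighting factor
remainder,0.12,ICRP 103 remainder (arithmetic mean of 13 remainder tissues)
gonads,0.08,ICRP 103 tissue weighting factor
bladder,0.04,ICRP 103 tissue weighting factor
oesophagus,0.04,ICRP 103 tissue weighting factor
liver,0.04,ICRP 103 tissue weighting factor
thyroid,0.04,ICRP 103 tissue weighting factor
bone_surface,0.01,ICRP 103 tissue weighting factor
brain,0.01,ICRP 103 tissue weighting factor
salivary_glands,0.01,ICRP 103 tissue weighting factor
skin,0.01,ICRP 103 tissue weighting factor
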