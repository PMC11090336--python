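age_group,genotype,n_male,n_female
younger,Val/Val,12,9
younger,Val/Met,7,10
younger,Met/Met,8,9
older,Val/Val,7,8
older,Val/Met,7,5
older,Met/Met,12,6
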