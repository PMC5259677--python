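case_id,resolution,n_detected,n_observed,two_way_distance,aa_detected,aa_total
1657_4V5H_AH4,5.8,6,6,1.94,25,30
1780_4V7E_AH4,5.5,5,5,1.88,24,28
1829_4V5H_AH4,5.6,8,6,2.11,25,30
1849_4V6K_AE6,8.25,7,6,2.34,24,40
1849_4V6K_AC6,,6,5,1.90,26,31
1849_4V6K_AG2,,6,6,2.74,31,52
5030_4V68_AF8,6.4,4,5,1.72,24,32
5036_4V69_AD5,6.7,5,5,1.73,23,29
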