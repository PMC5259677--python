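case_id,n_detected,n_observed,two_way_distance,aa_detected,aa_total
1G7K_A13,11,11,1.80,85,124
1QD5_A17,12,12,1.93,99,140
1QJP_A,8,8,1.78,70,107
1RRX_A12,12,11,1.81,86,118
1TX2_B,8,8,0.92,31,34
1UYN_XA12,12,12,1.83,144,189
2ERV_A10,8,8,1.17,74,94
2K0L_A,8,8,1.96,57,79
2LHF_A,8,8,1.44,61,79
2QOM_C,12,12,1.71,153,190
2VDF_AA28,10,10,1.61,144,172
2WJR_AA15,12,12,1.50,114,130
2X9K_AA15,14,14,1.63,151,188
3AEH_A15,12,12,1.85,141,194
3FID_A14,12,12,1.42,131,155
3GP6_A,8,8,1.94,60,88
4E1S_A13,12,12,1.39,118,136
4FQE_A,12,12,1.28,121,134
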