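case_id,n_detected,n_observed,two_way_distance,aa_detected,aa_total
2GUF_D23,21,22,2.03,230,296
2HDI_D23,22,22,1.93,226,296
2J1N_AA18,16,16,1.77,146,181
2MPR_A19,19,19,2.49,134,224
2POR_S117,12,16,2.53,94,178
2QDZ_C17,16,16,1.32,177,198
2YNK_AC20,20,18,2.26,133,194
3CSL_C23,23,22,2.59,171,300
3EMN_A20,20,19,1.83,135,183
3PRN_A17,15,17,1.67,131,162
3SYB_A19,19,18,2.12,155,220
4C00_AE17,17,16,2.37,121,202
4GEY_A18,19,16,2.33,116,189
4K3C_C18,18,16,2.43,126,193
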