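variable	cohort	mut_a	mut_b	wt_a	wt_b	printed_p
sex_f_m	CD	10	1	13	2	1.0000
sex_f_m	SCA	4	0	9	7	0.2487
invasive_noninv_inv	CD	3	8	4	11	1.0000
invasive_noninv_inv	SCA	4	0	12	4	0.5377
ki67_ge3_lt3	CD	4	7	3	12	0.4065
ki67_ge3_lt3	SCA	1	3	4	12	1.0000
remission_yes_no	CD	11	0	9	6	0.0237
histology_sparse_dense	CD	3	8	6	9	0.6828
histology_sparse_dense	SCA	2	2	10	6	1.0000
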