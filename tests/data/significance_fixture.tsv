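transcript_id	n_WT	n_KO	median_WT	median_KO	delta_median	p_adjusted
tx_a	30	25	60.0	45.0	-15.0	0.01
tx_b	30	30	60.0	45.0	-15.0	0.2
tx_c	30	30	60.0	55.0	-5.0	0.01
tx_d	15	40	60.0	48.0	-12.0	0.01
tx_e	20	20	50.0	60.0	10.0	0.049
tx_f	100	100	80.0	50.0	-30.0	0.05
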