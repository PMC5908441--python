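field	TV58g	TV50a	MS14i	MS19b	AJ50j	AJ50h	AJ44j	MS74b
max_speed_cm_s	u	u	6.3	18.8	17.2	16.5	12.0	u
rate_lm	48.4 ± 6.0	51.4 ± 10.6	67.8 ± 12.9	43.4 ± 9.3	65.3 ± 11.7	33.6 ± 9.6	76.7 ± 11.0	55.0 ± 11.0
rate_sm	41.6 ± 5.3	47.6 ± 8.8	51.0 ± 12.7	33.3 ± 8.6	42.5 ± 9.7	27.7 ± 3.8	43.8 ± 9.9	u
rate_ws	47.1 ± 9.3	u	47.9 ± 9.0	33.2 ± 8.0	34.7 ± 6.1	24.3 ± 4.9	37.7 ± 2.5	34.2 ± 14.9
rate_im	44.2 ± 12.0	46.3 ± 10.5	48.2 ± 10.0	31.9 ± 5.2	46.6 ± 9.9	25.4 ± 7.6	38.1 ± 6.8	37.6 ± 16.0
burst_incidence_lm	5.0 ± 1.0	6.3 ± 0.9	3.8 ± 1.7	4.4 ± 0.9	6.7 ± 1.0	4.1 ± 1.7	6.2 ± 1.9	5.2 ± 1.3
burst_incidence_sm	4.4 ± 0.5	5.7 ± 1.0	4.7 ± 1.1	3.6 ± 1.1	5.5 ± 1.3	3.3 ± 0.8	5.6 ± 1.2	u
burst_incidence_ws	4.4 ± 0.9	u	4.6 ± 1.1	4.4 ± 1.3	4.6 ± 1.0	2.8 ± 0.8	6.0 ± 1.0	2.9 ± 1.4
burst_incidence_im	4.2 ± 1.2	5.0 ± 0.9	4.9 ± 0.9	4.5 ± 1.3	5.4 ± 1.0	3.1 ± 1.3	5.3 ± 1.1	3.5 ± 0.9
theta_phase_deg	159	176	152	167	177	264	130	233
theta_r	0.37	0.50	0.23	0.27	0.51	0.35	0.44	0.34
theta_rayleigh_p	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001
theta_n_spikes	1081	2679	6659	5143	1743	1413	860	578
spikes_per_cycle	6.8 ± 3.1	6.7 ± 3.0	8.7 ± 4.2	7.2 ± 3.4	7.2 ± 3.1	4.6 ± 1.9	7.7 ± 3.3	8.1 ± 3.2
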