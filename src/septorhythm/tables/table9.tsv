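field	MS17k	MS58i	MS24a	MS84f	TV78d	TV78k	TV85e	TV86b
theta_phase_deg	176	133	178	177	261	163	160	243
theta_r	0.29	0.42	0.43	0.31	0.38	0.26	0.41	0.30
theta_rayleigh_p	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001
theta_n_spikes	727	2869	3287	4624	2154	1291	2792	1292
spikes_per_cycle	9.0 ± 3.7	7.6 ± 3.9	6.8 ± 3.9	8.8 ± 2.7	5.3 ± 3.4	7.5 ± 4.1	7.3 ± 4.4	9.6 ± 3.6
gamma_phase_deg	u	u	155	u	144	u	207	u
gamma_r	u	u	0.3210	u	0.12	u	0.04	u
gamma_rayleigh_p	0.1919	0.6089	<0.0001	0.0870	<0.0001	0.3506	0.0417	0.4627
gamma_n_spikes	1003	1032	284	1227	871	1457	2000	1274
n_swr	24	6	55	0	24	46	19	42
swr_rate_inside	69.35	u	27.47	u	3.75	19.67	u	4.48
swr_lambda_outside	46.33	u	36.92	u	40.71	31.92	u	42.31
swr_poisson_p	0.0004	u	0.0176	u	<0.0001	0.0068	u	<0.0001
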