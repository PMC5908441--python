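field	TV77q	TV78l
rate_lm	38.4 ± 12.2	25.3 ± 1.7
rate_sm	22.5 ± 7.6	16.7 ± 5.8
rate_ws	16.0 ± 7.5	23.3 ± 8.6
rate_im	15.6 ± 8.1	21.6 ± 6.2
burst_incidence_lm	3.7 ± 1.4	2.5 ± 0.6
burst_incidence_sm	2.6 ± 0.9	1.5 ± 1.2
burst_incidence_ws	1.5 ± 1.1	1.3 ± 1.2
burst_incidence_im	1.5 ± 1.2	1.8 ± 1.2
burst_duration_lm	69.7, 73.6	85.9, 96.2
burst_duration_sm	75.9, 40.5	64.9, 19.6
burst_duration_ws	74.3, 38.6	109.3, 102.4
burst_duration_im	69.0, 48.1	86.3, 60.5
interburst_lm	196.6, 206.7	537.7, 412.8
interburst_sm	332.0, 250.9	457.3, 418.8
interburst_ws	427.4, 588.3	427.3, 214.8
interburst_im	445.5, 615.9	393.4, 384.6
intraburst_lm	85.3 ± 27.1	69.8 ± 35.9
intraburst_sm	78.1 ± 28.3	65.6 ± 15.9
intraburst_ws	82.9 ± 27.2	69.3 ± 13.3
intraburst_im	85.7 ± 31.1	64.1 ± 15.6
theta_phase_deg	230	u
theta_r	0.27	u
theta_rayleigh_p	<0.0001	0.2819
theta_n_spikes	1206	505
spikes_per_cycle	3.1 ± 2.7	u
n_swr	50	61
swr_rate_inside	6.20	0.65
swr_lambda_outside	16.05	21.73
swr_poisson_p	0.0025	<0.0001
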