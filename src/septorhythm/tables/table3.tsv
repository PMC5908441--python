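field	TV58g	TV50a	MS14i	MS19b	AJ50j	AJ50h	AJ44j	MS74b
burst_duration_lm	87.0, 79.8	66.8, 30.5	121.0, 193.0	96.2, 57.5	63.2, 22.6	70.1, 36.3	68.2, 48.9	80.1, 40.1
burst_duration_sm	86.7, 47.5	71., 42.0	84.2, 56.7	85.7, 53.4	54.0, 23.8	65.2, 56.3	70.1, 38.3	u
burst_duration_ws	91.8, 77.1	u	91.7, 61.5	92.0, 56.8	59.2, 30.2	68.3, 35.5	52.4, 30.3	91.5, 91.9
burst_duration_im	94.6, 65.5	70.2, 46.0	81.1, 48.9	100.0, 57.3	57.8, 33.3	73.9, 33.7	68.6, 42.7	97.0, 75.0
ks_p_burst_duration	0.5928	0.0021	<0.0001	0.6573	0.0003	0.3998	0.1947	0.0293
interburst_lm	187.7, 80.9	146.0, 35.2	179.6, 162.5	193.5, 91.8	135.8, 41.3	160.0, 148.9	129.0, 52.1	155.3, 86.4
interburst_sm	214.2, 81.2	159.9, 49.3	178.7, 99.1	230.1, 166.5	159.9, 66.1	257.6, 209.6	158.2, 67.6	u
interburst_ws	205.1, 100.3	u	189.9, 105.1	255.4, 180.0	178.1, 137.8	291.7, 315.5	157.3, 73.9	254.5, 229.1
interburst_im	203.3, 94.5	177.3, 92.3	180.3, 87.5	238.3, 161.8	163.3, 66.2	255.8, 201.0	161.5, 61.7	249.0, 135.2
ks_p_interburst	0.0725	<0.0001	0.0039	<0.0001	<0.0001	<0.0001	<0.0001	<0.0001
intraburst_lm	95.9 ± 22.1	111.4 ± 24.8	95.8 ± 24.4	83.7 ± 24.6	136.1, 27.2	75.9 ± 23.6	131.4 ± 30.9	95.2 ± 20.2
intraburst_sm	84.9 ± 19.5	105.7 ± 24.5	99.7 ± 30.0	82.8 ± 27.5	121.0, 27.2	79.2 ± 17.7	96.0 ± 24.5	u
intraburst_ws	96.6 ± 24.3	u	93.1 ± 24.3	80.7 ± 22.7	110.6, 27.4	71.8 ± 10.2	96.4 ± 13.6	75.6 ± 16.1
intraburst_im	94.7 ± 22.8	113.1 ± 34.0	100.6 ± 28.0	77.6 ± 19.7	124.0, 32.6	78.1 ± 16.8	89.3 ± 18.2	79.3 ± 22.9
ks_p_intraburst	0.3102	0.0693	0.0357	0.0180	<0.0001	0.0602	<0.0001	<0.0001
gamma_phase_deg	u	u	164	158	u	191	u	u
gamma_r	u	u	0.04	0.25	u	0.19	u	u
gamma_rayleigh_p	u	0.0860	0.0008	<0.0001	0.6225	<0.0001	0.0799	0.4700
gamma_n_spikes	u	1240	3553	2052	1445	398	579	437
n_swr	34	40	57	58	0	0	0	16
swr_rate_inside	57.08	31.37	57.71	4.88	u	u	u	u
swr_lambda_outside	44.82	49.14	48.96	33.16	u	u	u	u
swr_poisson_p	0.0181	0.0015	0.0238	<0.0001	u	u	u	u
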