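field	MS17k	MS58i	MS24a	MS84f	TV78d	TV78k	TV85e	TV86b
max_speed_cm_s	9.9	u	16.8	u	14.3	4.5	u	u
rate_lm	51.6 ± 25.5	80.9 ± 20.2	48.7 ± 10.7	65.2 ± 7.5	31.5 ± 11.9	60.6 ± 12.5	87.6 ± 14.9	67.9 ± 9.1
rate_sm	51.8 ± 13.8	42.3 ± 9.1	50.1 ± 11.7	56.0 ± 10.9	41.6 ± 18.3	34.4 ± 12.1	47.3 ± 14.3	49.5 ± 6.4
rate_ws	46.7 ± 13.0	52.1 ± 14.7	44.2 ± 11.5	48.9 ± 11.6	u	30.3 ± 15.5	50.1 ± 10.1	55.1 ± 9.3
rate_im	44.6 ± 13.8	52.1 ± 14.7	33.7 ± 8.8	48.4 ± 9.2	39.5 ± 9.8	33.6 ± 9.6	58.0 ± 13.0	37.0 ± 9.7
burst_incidence_lm	3.3 ± 2.2	6.6 ± 1.0	5.3 ± 1.4	5.1 ± 1.5	3.6 ± 1.3	3.6 ± 1.0	7.0 ± 1.4	5.3 ± 1.2
burst_incidence_sm	4.7 ± 1.0	4.9 ± 1.4	4.0 ± 0.9	4.6 ± 1.4	4.0 ± 1.1	3.3 ± 0.9	5.2 ± 1.5	5.0 ± 0.0
burst_incidence_ws	4.7 ± 1.3	u	3.4 ± 1.0	4.8 ± 1.3	u	2.8 ± 1.0	5.4 ± 1.1	u
burst_incidence_im	4.3 ± 1.2	4.9 ± 1.1	3.3 ± 1.2	4.8 ± 1.1	3.8 ± 1.0	3.3 ± 1.0	5.3 ± 1.1	u
burst_duration_lm	86.7, 115.8	70.2, 22.0	57.4, 36.8	86.4, 111.8	76.9, 39.4	156.3, 101.6	64.1, 34.0	89.6, 62.7
burst_duration_sm	90.8, 84.8	67.3, 47.2	107.0, 84.0	99.2, 77.6	90.0, 57.6	112.9, 70.2	62.5, 25.9	101.2, 77.0
burst_duration_ws	82.9, 74.0	76.7, 57.4	97.3, 65.1	96.7, 93.0	u	118.3, 50.0	62.1, 43.4	96.5, 70.3
burst_duration_im	84.4, 67.7	76.7, 57.4	94.1, 73.0	94.3, 69.9	95.3, 72.1	112.6, 72.3	65.9, 45.1	75.8, 43.4
ks_p_burst_duration	0.3902	0.0024	<0.0001	0.0294	<0.0001	<0.0001	0.5547	0.0045
interburst_lm	166.6, 155.2	133.1, 31.1	155.6, 96.5	147.4, 115.9	197.8, 163.9	233.8, 155.6	133.0, 32.1	163.1, 91.8
interburst_sm	190.7, 135.2	169.8, 117.3	236.9, 138.7	178.1, 86.8	206.6, 136.8	267.4, 163.5	163.1, 73.2	181.8, 84.8
interburst_ws	197.9, 95.7	u	259.9, 194.5	189.1, 92.9	u	311.2, 299.0	159.7, 79.0	185.4, 95.3
interburst_im	201.8, 117.9	170.7, 100.1	260.7, 186.0	187.2, 88.1	238.1, 136.9	267.6, 137.6	159.9, 91.8	194.4, 113.2
ks_p_interburst	0.0484	<0.0001	<0.0001	<0.0001	<0.0001	0.0130	<0.0001	<0.0001
intraburst_lm	103.4 ± 35.6	141.9, 24.7	144.3, 46.8	105.1, 23.8	83.3, 22.9	81.8, 17.9	150.2, 32.8	119.4, 32.4
intraburst_sm	94.2 ± 28.5	101.9, 26.1	104.4, 35.8	89.3, 27.0	87.4, 22.8	68.0, 14.6	117.9, 28.2	96.3, 24.6
intraburst_ws	95.6 ± 38.8	u	97.8, 25.9	88.9, 24.2	u	70.8, 17.8	118.2, 26.9	105.0, 26.8
intraburst_im	95.0 ± 27.3	101.9, 30.3	82.5, 27.4	86.9, 22.7	89.4, 27.2	72.4, 19.8	135.5, 39.0	96.3, 25.4
ks_p_intraburst	0.0914	<0.0001	<0.0001	<0.0001	0.0449	<0.0001	0.0003	<0.0001
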