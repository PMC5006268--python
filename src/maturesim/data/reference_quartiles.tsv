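source	feature	mtp	q1	median	q3
mea	spike_rate	1	2.71	9.53	36.26
mea	burst_rate	1	0.07	0.26	1.08
mea	burst_duration_s	1	0.87	5.25	12.65
mea	spikes_per_burst	1	1.57	3.16	4.96
mea	spike_rate	2	8.11	16.99	49.30
mea	burst_rate	2	0.09	0.39	0.99
mea	burst_duration_s	2	1.50	2.50	9.65
mea	spikes_per_burst	2	2.00	5.00	11.40
mea	spike_rate	3	14.92	39.45	144.64
mea	burst_rate	3	0.88	1.42	5.22
mea	burst_duration_s	3	2.05	6.98	7.55
mea	spikes_per_burst	3	3.08	6.33	7.62
mea	spike_rate	4	57.10	91.21	163.21
mea	burst_rate	4	0.89	4.19	7.19
mea	burst_duration_s	4	0.97	2.79	4.45
mea	spikes_per_burst	4	4.16	7.00	19.31
mea	spike_rate	5	109.76	148.48	224.46
mea	burst_rate	5	4.29	5.66	10.69
mea	burst_duration_s	5	2.35	3.71	16.23
mea	spikes_per_burst	5	12.18	18.67	45.68
mea	spike_rate	6	53.68	106.90	113.65
mea	burst_rate	6	2.24	2.59	4.79
mea	burst_duration_s	6	1.44	12.68	17.97
mea	spikes_per_burst	6	7.19	20.00	24.68
sim	spike_rate	1	10.98	11.39	11.98
sim	burst_rate	1	0.28	0.40	0.57
sim	burst_duration_s	1	13.99	18.09	21.43
sim	spikes_per_burst	1	4.15	5.61	6.38
sim	spike_rate	2	14.19	15.67	17.74
sim	burst_rate	2	0.40	0.47	0.62
sim	burst_duration_s	2	6.85	10.17	27.46
sim	spikes_per_burst	2	4.02	4.56	10.95
sim	spike_rate	3	23.04	24.17	26.15
sim	burst_rate	3	0.42	0.60	0.84
sim	burst_duration_s	3	11.87	16.56	18.36
sim	spikes_per_burst	3	7.00	9.01	10.47
sim	spike_rate	4	56.02	57.16	60.39
sim	burst_rate	4	2.28	2.67	3.15
sim	burst_duration_s	4	10.05	11.14	12.65
sim	spikes_per_burst	4	13.07	14.94	16.46
sim	spike_rate	5	95.83	100.71	104.10
sim	burst_rate	5	4.60	5.34	6.26
sim	burst_duration_s	5	4.18	5.13	5.93
sim	spikes_per_burst	5	11.43	13.37	14.15
sim	spike_rate	6	49.64	54.16	56.28
sim	burst_rate	6	1.63	2.06	2.46
sim	burst_duration_s	6	9.67	12.96	15.75
sim	spikes_per_burst	6	12.57	15.14	17.97
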