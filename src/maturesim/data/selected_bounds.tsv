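mtp	connection_probability	c_upper	y_exc_upper	y_inh_upper
1	0.01	0.07	0.1	-0.1
2	0.02	0.08	0.1	-0.1
3	0.04	0.08	0.3	-0.1
4	0.06	0.09	0.5	-0.1
5	0.08	0.09	0.5	-0.1
6	0.10	0.09	0.3	-0.1
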