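trait	sex	n_fids	n_obs	mean	sd	h2	h2_se	v_p	v_e
CC	female	1580	287063	19.6	3.7	0.11	0.01	14.2	11.7
CC	male	889	287111	12.1	2.9	0.10	0.02	8.9	6.9
rbar	female	1580	287063	8.06e-3	1.87e-3	0.06	0.01	3.8e-3	3.1e-3
rbar	male	889	287111	1.01e-3	0.56e-3	0.11	0.03	0.4e-3	0.2e-3
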