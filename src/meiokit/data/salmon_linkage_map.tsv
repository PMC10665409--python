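chrom	n_markers	length_mb	male_cM	female_cM	female_male_ratio	male_rate	female_rate
ssa1	2828	174.50	101.15	130.32	1.29	0.58	0.75
ssa2	749	95.48	19.54	104.45	5.34	0.20	1.09
ssa3	1417	105.78	59.92	107.26	1.79	0.57	1.01
ssa4	1485	90.54	56.88	101.11	1.78	0.63	1.12
ssa5	1246	92.79	62.60	103.35	1.65	0.67	1.11
ssa6	1255	96.06	54.88	115.71	2.11	0.57	1.20
ssa7	852	68.86	67.55	101.37	1.50	0.98	1.47
ssa8	300	28.86	2.01	56.40	28.13	0.07	1.95
ssa9	2333	161.28	55.68	97.65	1.75	0.35	0.61
ssa10	1881	125.88	56.54	80.23	1.42	0.45	0.64
ssa11	1392	111.87	50.92	78.75	1.55	0.46	0.70
ssa12	1485	101.68	55.15	79.27	1.44	0.54	0.78
ssa13	1611	114.42	60.33	76.21	1.26	0.53	0.67
ssa14	1557	101.98	60.94	69.79	1.15	0.60	0.68
ssa15	1524	110.67	55.84	70.27	1.26	0.50	0.63
ssa16	1302	96.49	48.83	64.02	1.31	0.51	0.66
ssa17	681	87.49	3.79	60.96	16.09	0.04	0.70
ssa18	1067	84.08	45.04	63.04	1.40	0.54	0.75
ssa19	1157	88.11	52.57	59.48	1.13	0.60	0.68
ssa20	1331	96.85	53.81	61.61	1.14	0.56	0.64
ssa21	962	59.82	49.88	54.37	1.09	0.83	0.91
ssa22	1122	63.82	52.31	56.56	1.08	0.82	0.89
ssa23	949	52.46	55.52	55.48	1.00	1.06	1.06
ssa24	925	49.35	52.75	54.53	1.03	1.07	1.10
ssa25	888	54.39	50.67	54.06	1.07	0.93	0.99
ssa26	593	55.99	48.91	53.05	1.08	0.87	0.95
ssa27	825	45.31	48.75	53.57	1.10	1.08	1.18
ssa28	606	41.47	48.55	56.60	1.17	1.17	1.36
ssa29	709	43.05	51.66	54.34	1.05	1.20	1.26
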