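site	distance_to_active_site_A	svm_score	junction_distance	conservation_rank	splicing
C64	10.01	0.41	>2	0.55	X
S112	6.74	0.11	>2	0.85	X
T113	8.99	0.36	2	0.34
S124	10.58	-1.34	2	0.68	X
T134	17.40	0.66	1	0.30	X
S135	17.22	-1.13	1	0.00	X
T140	21.71	-0.02	2	0.81
T151	9.71	-0.29	>2	0.09
T152	9.37	0.19	>2	0.43
S158	8.15	0.34	2	0.91	X
T164	10.33	0.21	2	0.96	X
S170	12.06	-0.45	>2	1.00	X
T173	18.16	-1.47	1	0.49
S174	17.45	-0.32	2	0.36	X
T177	13.89	-1.38	1	0.32
S178	16.44	-0.01	1	0.62	X
T182	17.55	-0.15	>2	0.77
T199	11.61	-0.60	1	0.23
T204	11.54	-0.16	>2	0.51
C206	6.43	-0.55	>2	0.70	X
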