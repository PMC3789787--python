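plasmid_id	nt_change	substitution	ddg	category	rate_400	sd_400	flag_400	rate_4	sd_4	flag_4	rate_2	sd_2	flag_2	rate_1	sd_1	flag_1
pJR2985	194, A>T	H65L	1.2	nonfunctional	0			n/d			n/d			n/d		
pJR2993	424, AT>GC	I142A	3.7	nonfunctional	0			n/d			n/d			n/d		
pJR2994	425, T>A	I142N	9.7	nonfunctional	0			n/d			n/d			n/d		
pJR2996	460, CT>GC	L154A	1.8	nonfunctional	0			n/d			n/d			n/d		
pJR2997	461, T>C	L154P	6.7	nonfunctional	0			n/d			n/d			n/d		
pJR2998	529, A>G	K177E	1.2	nonfunctional	0			n/d			n/d			n/d		
pJR3001	566, T>C	V189A	3.1	nonfunctional	0			n/d			n/d			n/d		
pJR3002	620, C>G	A207G	2.0	nonfunctional	0			n/d			n/d			n/d		
pJR3003	629, T>A	L210Q	4.2	nonfunctional	0			n/d			n/d			n/d		
pJR3005	659, T>G	L220R	14.4	nonfunctional	0			n/d			n/d			n/d		
pJR3007	684, C>A	N228K	5.5	nonfunctional	0			n/d			n/d			n/d		
pJR3008	718, AT>GC	I240A	2.1	nonfunctional	0			n/d			n/d			n/d		
pJR3012	755, T>C	V252A	2.6	nonfunctional	0			n/d			n/d			n/d		
pJR3013	772, G>C	G258R	13.7	nonfunctional	0			n/d			n/d			n/d		
pJR3018	829, AT>CC	I277P	5.1	nonfunctional	0			n/d			n/d			n/d		
pJR3023	967, T>G	W323G	6.3	nonfunctional	0			n/d			n/d			n/d		
pJR3035	1153, TTC>CAA	F385Q	5.0	nonfunctional	0			n/d			n/d			n/d		
pJR3038	1268, T>C	L423P		nonfunctional	0			n/d			n/d			n/d		
pJR3040	1370, G>A	G457E		nonfunctional	0			n/d			n/d			n/d		
pJR2988	353, T>G	V118G	1.9	sensitive	0.91	0.04		0.81	0.25		0.49	0.23	*	0.39	0.07	**
pJR2991	379, A>G	I127V	1.5	sensitive	1.22	0.11		1.25	0.07	*	1.35	0.15		0.97	0.08	
pJR2995	424, A>G	I142V	1.3	sensitive	0.66	0.03	**	0.68	0.07	*	0.53	0.07		0.38	0.10	
pJR2999	541, CT>GC	L181A	3.1	sensitive	0.92	0.23		0.91	0.12		0.56	0.11		0.34	0.22	*
pJR3000	562, A>G	I188V	1.0	sensitive	1.19	0.23		1.41	0.38		1.42	0.53		1.93	0.64	*
pJR3006	674, A>G	N225S	1.4	sensitive	0.71	0.10	**	0.62	0.11	**	0.35	0.09	**	0.36	0.07	**
pJR3015	799, A>G	K267E	0.9	sensitive	0.68	0.38		0.67	0.39		0.47	0.28	**	0.26	0.15	**
pJR3020	856, AT>GC	I286A	1.1	sensitive	0.52	0.10		0.43	0.05	*	0.18	0.05	*	0.13	0.11	*
pJR3021	877, C>G	L293V	1.1	sensitive	0.57	0.08		0.50	0.05	*	0.17	0.04	*	0.25	0.06	*
pJR3024	1012, CT>GC	L338A	1.7	sensitive	0.98	0.11		0.93	0.17		0.77	0.13	*	0.74	0.14	
pJR3026	1034, T>C	L345P	-1.2	sensitive	0.57	0.04	**	0.49	0.07	**	0.16	0.03	**	0.20	0.14	**
pJR3027	1061, T>G	V354G	7.5	sensitive	0.67	0.09	**	0.72	0.05	**	0.48	0.09	**	0.54	0.10	**
pJR3031	1112, T>C	V371A	2.7	sensitive	1.15	0.29		1.15	0.37		1.32	0.20	*	1.95	0.54	
pJR3036	1153, T>C	F385L	5.5	sensitive	0.85	0.15		0.72	0.05	**	0.37	0.07	**	0.37	0.03	**
pJR2986	250, A>G	I84V	1.0	benign	0.99	0.05		1.10	0.28		1.13	0.24		1.31	0.34	
pJR2990	370, CT>GC	L124A	2.3	benign	0.83	0.06		1.00	0.06		0.97	0.07		1.12	0.11	
pJR2989	370, C>G	L124V	2.1	benign	0.76	0.16		1.10	0.18		1.09	0.10		1.62	0.45	
pJR2992	418, G>A	D140N	3.0	benign	1.13	0.28		0.93	0.11		0.86	0.08		0.71	0.07	
pJR3004	640, A>G	I214V	1.1	benign	0.89	0.18		1.16	0.19		1.07	0.17		1.11	0.08	
pJR3009	718, A>G	I240V	1.0	benign	0.90	0.24		1.14	0.21		0.90	0.05		1.02	0.33	
pJR3010	721, C>G	L241V	1.4	benign	1.01	0.13		1.03	0.19		0.91	0.19		0.92	0.41	
pJR3011	742, CT>GC	L248A	1.2	benign	0.81	0.08		0.84	0.11		0.73	0.14		0.71	0.08	
pJR3014	791, T>C	I264T	3.3	benign	1.12	0.33		1.13	0.20		1.05	0.33		1.08	0.31	
pJR3016	800, A>T	K267M	-1.8	benign	1.02	0.18		1.07	0.15		1.10	0.21		1.15	0.18	
pJR3017	811, A>G	K271E	0.4	benign	0.87	0.18		0.89	0.28		0.80	0.20		0.87	0.31	
pJR3019	839, T>C	V280A	2.5	benign	1.10	0.30		1.12	0.27		1.13	0.23		1.41	0.21	
pJR3022	931, A>G	I311V	0.7	benign	1.03	0.15		1.33	0.50		1.12	0.44		1.41	0.75	
pJR3025	1023, A>T	Q341H	-2.5	benign	1.09	0.23		0.85	0.20		0.86	0.19		0.86	0.10	
pJR3028	1067, T>C	V356A	1.3	benign	0.98	0.12		1.04	0.06		0.94	0.00		0.92	0.08	
pJR3029	1070, C>G	A357G	1.6	benign	1.09	0.16		1.17	0.23		0.99	0.23		0.77	0.19	
pJR3030	1073, T>C	V358A	1.6	benign	0.92	0.10		0.90	0.05		0.87	0.14		0.73	0.08	
pJR3032	1115, T>C	V372A	2.7	benign	0.75	0.39		0.85	0.48		0.68	0.38		0.68	0.37	
pJR3033	1120, CT>GC	L374A	2.3	benign	1.09	0.10		1.06	0.20		1.17	0.24		1.28	0.22	
pJR3034	1147, A>T	T383S	1.1	benign	0.95	0.15		0.87	0.14		0.70	0.10		0.83	0.22	
pJR3037	1223, G>T	W408L		benign	1.04	0.03		1.13	0.17		1.19	0.16		1.08	0.10	
pJR3039	1298, A>T	H433L		benign	0.98	0.22		0.93	0.30		0.83	0.21		0.72	0.13	
pJR3041	1468, A>C	I490L		benign	0.86	0.49		0.74	0.42		0.74	0.43		0.87	0.49	
pJR3042	1646, A>G	D549G		benign	0.95	0.13		0.80	0.11		0.69	0.10		0.65	0.12	
pJR3043	1675, T>C	Y559H		benign	1.36	0.10		1.18	0.32		1.15	0.35		1.07	0.37	
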