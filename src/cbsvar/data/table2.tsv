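substitution	pyridoxine_ng_ml	dala_ug_ml	rate	sd
V118G	400	50	0.90	0.06
V118G	400	5	0.78	0.12
V118G	2	50	0.60	0.15
V118G	2	5	0.56	0.07
I142V	400	50	0.82	0.07
I142V	400	5	0.74	0.12
I142V	2	50	0.69	0.14
I142V	2	5	0.87	0.08
L181A	400	50	0.64	0.06
L181A	400	5	0.59	0.03
L181A	2	50	0.57	0.09
L181A	2	5	0.59	0.08
N225S	400	50	0.74	0.11
N225S	400	5	0.66	0.06
N225S	2	50	0.55	0.12
N225S	2	5	0.45	0.07
K267E	400	50	0.61	0.00
K267E	400	5	n/d	
K267E	2	50	0.57	0.18
K267E	2	5	n/d	
I286A	400	50	0.64	0.03
I286A	400	5	0.58	0.02
I286A	2	50	0.46	0.06
I286A	2	5	0.34	0.05
L293V	400	50	0.69	0.07
L293V	400	5	0.67	0.10
L293V	2	50	0.47	0.07
L293V	2	5	0.36	0.06
L345P	400	50	0.58	0.01
L345P	400	5	0.07	0.03
L345P	2	50	0.25	0.06
L345P	2	5	0.05	0.01
F385L	400	50	0.77	0.05
F385L	400	5	0.69	0.07
F385L	2	50	0.58	0.10
F385L	2	5	0.54	0.11
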