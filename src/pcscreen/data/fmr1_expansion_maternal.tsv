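cgg_lower	cgg_upper	expansion_prob
55	59	0.037
60	64	0.053
65	69	0.077
70	74	0.311
75	79	0.578
80	84	0.729
85	89	0.896
90	94	0.939
95	99	0.981
100	200	0.981
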