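year	mean	sd	cv_percent	min	max	kurt	skew
2022	3.18	1.28	40.25	0.17	8.33	0.93	0.64
2023	5.20	2.07	39.82	0.67	10.17	0.64	0.93
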