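# Published arm sizes estimated for each tammar wallaby autosome.
# chromosome	arm	size_mb	size_cm
1	p	90.479	65.00
1	q	395.521	277.58
2	p	44.00	29.64
2	q	323.00	217.34
3	p	141.992	94.00
3	q	213.008	148.39
4	p	109.093	68.73
4	q	230.907	117.03
5	p	66.812	53.52
5	q	273.188	179.17
6	p	137.164	64.35
6	q	148.836	69.83
7	p	68.960	60.65
7	q	64.040	63.13
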