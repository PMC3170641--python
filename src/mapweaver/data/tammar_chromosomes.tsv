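# Published flow-karyotype Mb sizes and full-coverage linkage lengths (cM)
# for the tammar wallaby (Macropus eugenii) chromosomes.
# name	size_mb	size_cm
1	486	342.58
2	367	246.98
3	355	242.39
4	340	185.76
5	340	232.68
6	286	134.18
7	133	123.78
X	150	189.75
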