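# Published cM offsets anchoring the partial-coverage tammar wallaby linkage
# maps to the p-telomere (offset = m% x linkage-map length).
# chromosome	offset_cm
1	12.21
2	29.10
3	7.33
4	16.34
5	3.60
6	3.53
7	1.49
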