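# Human chromosome sizes (Mb, Ensembl GRCh37 assembly lengths, rounded)
# used as flow-karyotype calibration references.
# name	size_mb
HSA1	249
HSA2	243
HSA3	198
HSA4	191
HSA5	181
HSA6	171
HSA7	159
HSA8	146
HSA9	141
HSA10	136
HSA11	135
HSA12	134
HSA13	115
HSA14	107
HSA15	103
HSA16	90
HSA17	81
HSA18	78
HSA19	59
HSA20	63
HSA21	48
HSA22	51
HSAX	155
HSAY	59
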