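# Published evolutionary-breakpoint locations (Mb from p-telomere) between
# blocks of conserved synteny in tammar wallaby autosomes. ref = reference
# genome the flanking blocks were sized in (MDO opossum, HSA human).
# chromosome	id	mb	ref
1	1	10.457	MDO
1	2	18.164	MDO
1	3	49.991	MDO
1	4	74.210	MDO
1	5	90.479	MDO
1	6	124.826	MDO
1	7	153.320	MDO
1	8	165.519	MDO
1	9	191.563	MDO
1	10	207.073	MDO
1	11	230.327	MDO
1	12	234.147	MDO
1	13	236.706	MDO
1	14	318.217	MDO
1	15	417.080	MDO
1	16	418.331	MDO
1	17	455.644	MDO
2	1	44.000	MDO
2	2	66.963	MDO
2	3	98.799	MDO
2	4	220.170	MDO
2	5	252.521	MDO
2	6	266.054	MDO
3	1	6.975	MDO
3	2	12.959	MDO
3	3	13.762	MDO
3	4	22.684	MDO
3	5	25.237	MDO
3	6	26.008	MDO
3	7	29.018	MDO
3	8	64.847	MDO
3	9	66.291	MDO
3	10	72.584	MDO
3	11	79.807	MDO
3	12	102.372	MDO
3	13	107.559	MDO
3	14	113.096	MDO
3	15	120.422	MDO
3	16	129.009	MDO
3	17	137.739	MDO
3	18	140.468	MDO
3	19	141.190	MDO
3	20	141.992	MDO
3	21	156.758	HSA
3	22	170.135	HSA
3	23	175.506	HSA
3	24	180.577	HSA
3	25	187.518	HSA
3	26	210.810	HSA
3	27	211.725	HSA
4	1	24.970	MDO
4	2	59.325	MDO
4	3	77.755	MDO
4	4	86.055	MDO
4	5	93.325	MDO
4	6	109.093	MDO
4	7	139.119	MDO
4	8	280.434	MDO
4	9	281.743	MDO
4	10	309.767	MDO
5	1	37.729	MDO
5	2	71.500	MDO
5	3	152.272	MDO
5	4	206.066	MDO
5	5	267.109	MDO
5	6	291.421	MDO
5	7	293.771	HSA
5	8	324.806	HSA
6	1	137.164	MDO
6	2	148.722	MDO
6	3	159.539	MDO
6	4	188.129	MDO
6	5	209.119	MDO
6	6	221.964	MDO
6	7	238.312	MDO
6	8	283.660	MDO
7	1	68.960	MDO
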