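table	chrom	status	OpenSea	Island	Shelf	Shore
global	Chr1	Hypomethylated	786	39	142	179
global	Chr1	Hypermethylated	57	636	10	210
global	Chr2	Hypomethylated	861	40	137	168
global	Chr2	Hypermethylated	36	568	5	154
global	Chr3	Hypomethylated	532	17	73	70
global	Chr3	Hypermethylated	30	430	15	155
global	Chr4	Hypomethylated	442	5	83	85
global	Chr4	Hypermethylated	12	462	7	120
global	Chr5	Hypomethylated	588	28	91	118
global	Chr5	Hypermethylated	62	541	4	116
global	Chr6	Hypomethylated	781	13	96	111
global	Chr6	Hypermethylated	75	503	17	201
global	Chr7	Hypomethylated	728	55	151	195
global	Chr7	Hypermethylated	50	533	21	162
global	Chr8	Hypomethylated	597	29	93	142
global	Chr8	Hypermethylated	26	502	7	164
global	Chr9	Hypomethylated	106	13	26	69
global	Chr9	Hypermethylated	12	177	5	28
global	Chr10	Hypomethylated	506	26	101	121
global	Chr10	Hypermethylated	40	573	5	116
global	Chr11	Hypomethylated	686	19	84	131
global	Chr11	Hypermethylated	41	448	4	147
global	Chr12	Hypomethylated	485	18	78	115
global	Chr12	Hypermethylated	43	357	20	109
global	Chr13	Hypomethylated	517	17	85	97
global	Chr13	Hypermethylated	29	372	11	170
global	Chr14	Hypomethylated	253	9	39	58
global	Chr14	Hypermethylated	13	220	5	74
global	Chr15	Hypomethylated	313	9	35	39
global	Chr15	Hypermethylated	9	219	4	34
global	Chr16	Hypomethylated	267	29	68	121
global	Chr16	Hypermethylated	35	295	15	59
global	Chr17	Hypomethylated	242	7	75	80
global	Chr17	Hypermethylated	27	229	4	46
global	Chr18	Hypomethylated	37	14	33	27
global	Chr18	Hypermethylated	1	161	4	22
global	Chr19	Hypomethylated	262	40	114	119
global	Chr19	Hypermethylated	37	524	18	147
global	Chr20	Hypomethylated	223	41	88	127
global	Chr20	Hypermethylated	2	385	5	85
global	Chr21	Hypomethylated	67	4	18	23
global	Chr21	Hypermethylated	5	88	0	20
global	Chr22	Hypomethylated	63	23	37	49
global	Chr22	Hypermethylated	1	98	3	21
mir	Chr1	Hypomethylated	5	0	0	0
mir	Chr1	Hypermethylated	0	1	0	2
mir	Chr2	Hypomethylated	1	0	0	0
mir	Chr2	Hypermethylated	0	0	0	0
mir	Chr3	Hypomethylated	6	0	0	0
mir	Chr3	Hypermethylated	1	1	0	0
mir	Chr4	Hypomethylated	0	0	0	0
mir	Chr4	Hypermethylated	0	0	0	0
mir	Chr5	Hypomethylated	1	0	0	0
mir	Chr5	Hypermethylated	0	0	0	0
mir	Chr6	Hypomethylated	5	0	0	0
mir	Chr6	Hypermethylated	0	0	0	0
mir	Chr7	Hypomethylated	12	0	0	0
mir	Chr7	Hypermethylated	0	0	0	0
mir	Chr8	Hypomethylated	1	0	0	1
mir	Chr8	Hypermethylated	0	3	0	7
mir	Chr9	Hypomethylated	1	0	0	0
mir	Chr9	Hypermethylated	0	0	0	0
mir	Chr10	Hypomethylated	0	1	3	2
mir	Chr10	Hypermethylated	0	0	0	0
mir	Chr11	Hypomethylated	2	0	0	0
mir	Chr11	Hypermethylated	2	12	0	0
mir	Chr12	Hypomethylated	0	0	0	0
mir	Chr12	Hypermethylated	0	0	0	0
mir	Chr13	Hypomethylated	12	0	3	1
mir	Chr13	Hypermethylated	0	0	0	0
mir	Chr14	Hypomethylated	25	1	1	2
mir	Chr14	Hypermethylated	0	0	0	0
mir	Chr15	Hypomethylated	1	1	0	1
mir	Chr15	Hypermethylated	0	5	0	0
mir	Chr16	Hypomethylated	1	0	0	0
mir	Chr16	Hypermethylated	0	0	0	1
mir	Chr17	Hypomethylated	0	0	0	0
mir	Chr17	Hypermethylated	0	0	0	0
mir	Chr18	Hypomethylated	20	0	0	0
mir	Chr18	Hypermethylated	0	0	0	0
mir	Chr19	Hypomethylated	5	0	0	0
mir	Chr19	Hypermethylated	0	0	0	0
mir	Chr20	Hypomethylated	0	0	0	0
mir	Chr20	Hypermethylated	0	18	0	1
mir	Chr21	Hypomethylated	0	0	0	0
mir	Chr21	Hypermethylated	0	0	0	0
mir	Chr22	Hypomethylated	0	0	0	0
mir	Chr22	Hypermethylated	1	0	0	0
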