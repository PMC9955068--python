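region	T	C	A	G	AT	at_skew	gc_skew
whole_genome	36.8	15.3	38.1	9.9	75.0	0.02	-0.21
PCGs	43.8	12.5	29.8	13.8	73.6	-0.19	0.05
codon_position_1	35.4	12.6	32.0	20.0	67.4	-0.05	0.24
codon_position_2	48.6	16.9	20.5	14.0	69.2	-0.41	-0.10
codon_position_3	47.4	8.1	37.0	7.6	84.3	-0.12	-0.03
rRNA	39.3	7.6	37.5	15.7	76.8	-0.02	0.35
tRNA	36.7	10.7	39.1	13.5	75.8	0.03	0.12
atp6	42.0	16.9	31.5	9.6	73.5	-0.14	-0.28
atp8	45.6	12.2	38.1	4.1	83.7	-0.09	-0.5
cox1	39.2	16.7	27.6	16.5	66.8	-0.17	-0.01
cox2	38.2	16.6	32.9	12.3	71.1	-0.07	-0.15
cox3	39.5	17.1	29.8	13.7	69.2	-0.14	0.11
cytb	39.5	16.6	31.6	12.4	71.0	-0.11	-0.14
nad1	48.7	8.5	26.2	16.6	74.9	-0.30	0.32
nad2	46.3	11.4	31.8	10.4	78.2	-0.19	-0.05
nad3	43.2	15.3	30.2	11.3	73.4	-0.18	-0.15
nad4	49.8	7.4	27.9	14.9	77.8	-0.28	0.34
nad4L	52.2	3.4	26.8	17.5	79.0	-0.32	0.67
nad5	44.5	8.1	31.8	15.6	76.2	-0.17	0.31
nad6	45.8	13.1	34.2	6.9	80.0	-0.15	-0.31
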