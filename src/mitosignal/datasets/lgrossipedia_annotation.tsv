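name	start	end	strand	kind	start_codon	stop_codon	size_published	ign_published
trnI	1	64	-	tRNA			64	46
trnQ	111	179	-	tRNA			69	9
trnM	189	253	+	tRNA			65	12
nd2	266	1216	+	PCG	ATA	TAG	951	-2
trnW	1215	1277	+	tRNA			63	-1
trnC	1277	1339	-	tRNA			63	0
trnY	1340	1405	-	tRNA			66	-5
cox1	1401	2939	+	PCG	ATA	TAA	1539	2
trnL1	2942	3006	+	tRNA			65	1
trnL2	3008	3069	+	tRNA			62	19
cox2	3089	3770	+	PCG	ATT	T	682	1
trnK	3771	3835	+	tRNA			65	0
trnD	3836	3898	+	tRNA			63	0
atp8	3899	4060	+	PCG	ATT	TAA	162	-4
atp6	4057	4720	+	PCG	ATA	T	664	0
cox3	4721	5508	+	PCG	ATG	T	788	-1
trnG	5509	5569	+	tRNA			61	63
nd3	5633	5990	+	PCG	ATA	T	358	3
trnA	5991	6052	+	tRNA			62	14
trnR	6067	6126	+	tRNA			60	-3
trnN	6124	6187	+	tRNA			64	0
trnS1	6188	6244	+	tRNA			57	0
trnE	6245	6307	+	tRNA			63	0
trnF	6308	6369	-	tRNA			62	0
nd5	6370	8041	-	PCG	ATT	T	1672	0
trnH	8042	8103	-	tRNA			62	0
nd4	8104	9403	-	PCG	ATG	T	1300	-1
nd4L	9403	9690	-	PCG	ATG	TAA	295	5
trnT	9696	9757	+	tRNA			62	0
trnP	9758	9820	-	tRNA			63	2
nd6	9823	10303	+	PCG	ATT	T	481	0
cytb	10304	11434	+	PCG	ATG	TAA	1131	-2
trnS2	11433	11499	+	tRNA			67	4
nd1	11504	12415	-	PCG	ATT	TAA	912	0
rrnL	12416	13738	-	rRNA			1323	0
trnV	13739	13806	-	tRNA			68	0
rrnS	13807	14586	-	rRNA			780	0
control_region	14589	15023	+	control_region			437	0
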