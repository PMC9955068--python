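gene	n_significant	proportion_published	at_max	at_mean	at_min	at_lg
nd2	554	61.4	78.2	68.6	57.2	78.2
cox1	588	65.1	66.8	61.7	54.1	66.8
cox2	368	40.8	71.1	64.2	53.7	71.1
atp8	123	13.6	83.7	70.2	47.8	83.7
atp6	435	48.2	73.5	64.8	54.6	73.5
cox3	597	66.1	69.2	62.3	51.2	69.2
nd3	350	38.8	76.8	68.7	56.8	73.5
nd5	710	78.6	76.2	66.5	54.8	76.2
nd4	692	76.6	77.8	67.0	55.1	77.8
nd4l	318	35.2	79.0	68.8	59.3	79.0
nd6	334	37.0	80.0	69.9	55.7	80.0
cytb	569	63.0	71.0	62.9	54.9	71.0
nd1	598	66.2	74.9	65.6	56.9	74.9
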