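gene	chrom	start	end	strand	base_mean	log2fc_male_over_female
Xist	chrX	103460373	103483233	-	275.66	-9.01
Ube1y1	chrY	818713	844224	+	232.95	9.02
Ddx3y	chrY	1260715	1286613	-	153.51	8.49
Bex1	chrX	136213972	136215513	-	168.51	-6.46
B230206F22Rik	chrX	103560910	103623754	-	34.38	-6.73
Sms	chrX	157443954	157492046	-	6792.54	-1.32
Eif2s3y	chrY	1010612	1028598	+	224.03	5.94
Rbm3	chrX	8138975	8145802	-	3756.52	-1.06
Fthl17	chrX	9033486	9034333	+	18.80	-5.67
Huwe1	chrX	151803282	151935417	+	2245.04	-0.81
Hprt	chrX	52988078	53021660	+	16923.45	-1.10
Eif2s3x	chrX	94188709	94212651	-	3306.76	-0.81
Syap1	chrX	162856843	162888462	-	2009.79	-1.13
Yy2	chrX	157566119	157568985	-	237.80	-2.07
Eif1ax	chrX	159372195	159385699	+	1826.30	-1.01
Ccng1	chr11	40748552	40755286	-	403.37	1.88
D7Ertd715e	chr7	59969577	59974431	-	365.59	-1.63
Atp6ap2	chrX	12587759	12617051	+	1103.98	-1.02
Uba1	chrX	20658421	20683179	+	4718.65	-0.82
Ddx3x	chrX	13281022	13293983	+	4503.61	-0.96
Timm8a1	chrX	134537258	134541629	-	3804.40	-1.20
Tsr2	chrX	151087094	151096543	-	2495.42	-0.76
Med14	chrX	12675371	12761973	-	725.57	-1.36
Usp38	chr8	80980733	81014906	-	1115.47	-0.99
Rhox5	chrX	37754608	37808878	+	27.14	-3.92
Gnl3l	chrX	150983133	151017322	-	910.96	-0.74
Kdm6a	chrX	18162667	18279358	+	481.77	-0.98
Als2cr11	chr1	59050506	59094900	-	9.24	4.02
Aen	chr7	78895927	78908833	+	513.62	0.99
Bcap31	chrX	73686183	73716175	-	1554.31	-0.63
Rbbp7	chrX	162760372	162779090	+	4036.08	-0.81
Acsl4	chrX	142317993	142390535	-	1262.01	-1.08
Idh3g	chrX	73778963	73786897	-	2177.00	-0.71
Lamp2	chrX	38405064	38456455	-	1278.91	-1.03
Rbmx	chrX	57383348	57393036	-	321.01	-0.91
Porcn	chrX	8193850	8206525	-	303.00	-1.11
Ssr4	chrX	73787028	73790828	+	798.15	-0.82
Otud5	chrX	7841831	7874858	+	728.02	-0.71
1810030O07Rik	chrX	12654884	12673546	-	134.89	-1.85
Atrx	chrX	105797615	105929372	-	707.08	-0.85
Prps1	chrX	140456603	140476140	+	8178.23	-0.77
Aifm1	chrX	48474944	48513426	-	387.98	-1.18
Gm14511	chrX	8975712	8976559	-	31.79	-3.30
Mapkapk2	chr1	131053704	131097543	-	46.62	2.72
Wdr45	chrX	7722249	7728201	+	2311.35	-0.85
Cox7b	chrX	106015700	106022450	+	116.54	-1.37
Mad2l1bp	chr17	46147385	46153551	-	1191.38	-0.92
Tmem56	chr3	121202010	121263316	-	542.41	-1.12
Rpl10	chrX	74270816	74273135	+	14774.94	-0.80
Cybasc3	chr19	10577723	10589830	+	465.93	0.85
Mtf1	chr4	124802549	124849800	+	512.08	-0.75
Cks2	chr13	51645232	51650662	+	2503.02	-0.66
Gm14458	chrX	8985900	8986755	-	5.13	-3.53
Cdca7	chr2	72476219	72486890	+	867.49	0.67
Pgrmc1	chrX	36598225	36606079	+	414.68	-1.00
Thoc2	chrX	41794994	41911901	-	381.21	-1.06
Cited1	chrX	102247440	102251769	-	3344.44	-0.53
Ypel5	chr17	72836704	72851195	+	2403.16	-0.70
Cdk16	chrX	20688493	20699877	+	802.78	-0.70
Dnajc28	chr16	91614257	91618999	-	10.24	3.47
Fmr1	chrX	68678555	68717961	+	587.22	-1.20
Gla	chrX	134588169	134601005	-	476.84	-1.06
Hnrnph2	chrX	134601286	134607054	+	879.15	-0.74
Mpp1	chrX	75109733	75130949	-	430.95	-1.07
Msl3	chrX	168654118	168673902	-	355.99	-1.12
Tbc1d25	chrX	8154472	8176181	-	258.99	-1.15
Trappc1	chr11	69323986	69325793	+	118.07	1.26
Utp14a	chrX	48256934	48282449	+	619.81	-0.73
Xiap	chrX	42067836	42109664	+	449.57	-0.86
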