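name	sequence	length	location	mfe	reads_plus	reads_minus
n006	UCCAGCUGGGCGGCCGUCUCC	21	chromosome_10:4733426:4733510:-	-38.6	1004	2798
n015	UUCUACCCAAGAGGCUGUGUA	21	chromosome_12:2479175:2479337:+	-93.9	84	264
n030	UCAAAGCUAGGAGCCAUGAAG	21	chromosome_14:139326:139506:+	-129.4	1347	4625
n046	UGUUCGGAGAUCCUUGUGCAUG	22	chromosome_16:3072001:3072107:-	-101.1	117	373
n051	UUGUUGACGACGUGCGCGGGC	21	chromosome_17:204043:204314:-	-129.8	41137	86593
n052	UGACACAUGGAACAACACAAC	21	chromosome_1:3554627:3554814:+	-150.9	287	505
n062	UGACAUGCGGUGAAUGUGAAU	21	chromosome_3:5564702:5564806:+	-105.4	15185	49088
n077	UCAUGAAGCGGAUACUGUGAA	21	chromosome_7:743887:744064:-	-103.91	1160	61
n083	UGGGCCUGUUGUGCACGUUCC	21	scaffold_28:208520:208678:-	-115.9	104	662
n084	UUGUGCCGGCCGACACUGCGG	21	scaffold_33:45408:45519:+	-49.9	77092	55878
n152	UGUACGGCGACCUGCAAAUGG	21	chromosome_10:5980485:5980652:+	-115.7	0	215
n168	AGGAUGACCGUCAUGAUUGCG	21	chromosome_13:4630466:4630659:-	-167	0	4628
n169	GUCAUUAAGACCGUCGGCAAU	21	chromosome_14:1815533:1815835:+	-206.26	0	170
n182	UAGGGCUUUUCGGAAGGGAGA	21	chromosome_17:4302900:4303054:+	-83.2	0	20463
n196	AUUCACAUUCACCGCAUGUCA	21	chromosome_3:5564693:5564816:+	-112	0	16257
n197	UCCUCCUCCUUGACGUCGGCG	21	chromosome_3:7309395:7309503:+	-50.1	0	321
n198	AGCAGCUUCCCACUCCCACGACC	23	chromosome_3:2104211:2104422:-	-66.5	0	415
n200	UGCGCAGCGGCAUCAUCUGGA	21	chromosome_4:2994696:2994894:-	-157.7	0	367
n207	UAGCAGUCUGAACCAAAGUCG	21	chromosome_7:2564607:2564734:+	-92.1	0	931
n209	UAUGGGCAGUUGUACUAAAUC	21	chromosome_7:4354369:4354571:+	-136.8	0	564
n212	UGGGCCUCACGGCGGCGGACC	21	chromosome_7:5449979:5450131:+	-140.8	0	270
n214	AGGGCCAACAGCUUUGACCGG	21	chromosome_7:5670376:5670487:+	-103.9	0	557
n222	AAUGCCAGCAGCUCCACGCCC	21	scaffold_18:257:618:+	-158.6	0	4384
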