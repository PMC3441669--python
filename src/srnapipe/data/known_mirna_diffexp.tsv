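mirna	plus_std	minus_std	log2fc	pvalue	sig
miR1144a.1	2.7916	6.8556	1.29619070	3.00277572489945e-05	**
miR1144b	67.7967	174.2123	1.36155953	4.25092513184362e-107	**
miR1147.1	645.5638	2759.7732	2.09591812	0	**
miR1148.2	5.2842	13.2071	1.32155674	3.68981982177614e-09	**
miR1149.1	0.1994	1.4114	2.82338960	0.00218223161858286	**
miR1149.2	35.3938	81.9645	1.21150253	4.19876393573889e-43	**
miR1150.3	0.3988	1.2098	1.60103125	0.0464712840858496	*
miR1153.1	1051.8453	2991.5522	1.50797170	0	**
miR1153.2*	44.8654	96.4822	1.10465953	9.53780690450724e-44	**
miR1155	18.9432	63.0108	1.73391907	3.9298538924937e-56	**
miR1156.1	31.6052	729.5141	4.52870201	0	**
miR1156.2	37.1885	302.6536	3.02473905	0	**
miR1158	1.5952	4.5368	1.50793775	0.000148301262915249	**
miR1159.2	0.7976	2.1172	1.40842024	0.0148368997880162	*
miR1160.2	0.6979	36.3951	5.70458009	4.07725858511646e-98	**
miR1160.3	0.0997	9.1744	6.52387649	1.14199975919422e-26	**
miR1164	1.5952	4.0327	1.33800877	0.00109191543677247	**
miR1166.1	0.6979	2.7221	1.96362783	0.000450528886605393	**
miR1172.1	232.3033	921.3694	1.98777004	0	**
miR1172.2	308.0760	1139.3365	1.88683570	0	**
miR906-3p	11.8644	42.5449	1.84234706	1.13973265129334e-41	**
miR909.1	0.3988	1.4114	1.82338960	0.0180099225615881	*
miR910	260.9175	924.7972	1.82554332	0	**
miR912	2830.5107	6891.9725	1.28385457	0	**
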