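locus	snp	pval	fdr_uncond	fdr_cond
1	rs2252865	4.76e-04	0.377	0.030
2	rs11579756	1.17e-04	0.203	0.037
3	rs4949526	1.11e-04	0.181	0.035
4	rs4650608	2.06e-04	0.257	0.028
5	rs4907103	9.77e-05	0.181	0.039
6	rs1625579	3.76e-06	0.065	0.011
7	rs11205362	1.11e-03	0.489	0.033
8	rs10495658	3.99e-05	0.115	0.044
9	rs813592	2.71e-05	0.095	0.014
10	rs10189138	1.42e-04	0.229	0.038
11	rs11692886	1.05e-04	0.181	0.035
12	rs6435387	4.28e-05	0.115	0.020
13	rs17180327	1.29e-05	0.080	0.038
14	rs17662626	7.79e-05	0.161	0.030
15	rs2675968	5.64e-05	0.143	0.021
16	rs4663627	1.31e-04	0.203	0.033
17	rs13072940	1.27e-05	0.080	0.013
18	rs4687657	1.56e-04	0.229	0.028
19	rs11130874	9.45e-06	0.077	0.030
20	rs9838229	2.89e-05	0.104	0.045
21	rs13150700	2.77e-04	0.286	0.048
22	rs9379780	3.78e-06	0.065	0.024
22	rs198829	2.18e-05	0.088	0.027
23	rs7749823	1.32e-07	0.014	0.005
23	rs17693963	1.87e-07	0.022	0.001
23	rs13190937	1.23e-04	0.203	0.033
23	rs3130893	3.83e-06	0.065	0.006
23	rs2523722	2.54e-07	0.025	0.001
23	rs2596565	9.33e-06	0.077	0.009
23	rs2284178	3.31e-04	0.316	0.036
23	rs805294	1.11e-04	0.181	0.039
23	rs9268858	1.66e-05	0.084	0.041
23	rs9268862	6.21e-07	0.037	0.002
23	rs502771	2.97e-05	0.104	0.039
23	rs9276601	3.07e-05	0.104	0.015
23	rs7383287	2.71e-05	0.095	0.019
23	rs1480380	1.06e-05	0.077	0.010
24	rs9462875	1.61e-04	0.229	0.036
25	rs7787274	3.27e-04	0.316	0.028
26	rs12543276	1.38e-04	0.203	0.046
27	rs7004633	1.70e-07	0.018	0.005
28	rs2254884	1.17e-04	0.203	0.032
29	rs6602217	2.29e-05	0.095	0.015
30	rs7084499	1.74e-04	0.229	0.040
31	rs2153522	7.92e-04	0.449	0.046
32	rs7895695	3.57e-05	0.115	0.018
33	rs2298278	1.24e-03	0.527	0.037
33	rs10883817	1.13e-05	0.080	0.020
33	rs11191580	1.71e-06	0.049	0.005
34	rs4356203	5.48e-05	0.128	0.029
35	rs676318	1.41e-05	0.080	0.023
36	rs6591348	1.16e-05	0.080	0.027
37	rs17126243	1.29e-05	0.080	0.027
38	rs11222395	1.36e-04	0.203	0.032
39	rs7106715	6.52e-05	0.143	0.039
40	rs7972947	5.32e-07	0.035	0.013
41	rs1006737	3.52e-05	0.104	0.022
42	rs4517638	1.10e-05	0.077	0.015
43	rs961196	3.07e-03	0.662	0.044
44	rs1502404	1.04e-03	0.489	0.040
45	rs724729	4.70e-05	0.128	0.038
46	rs1869901	2.03e-04	0.257	0.039
47	rs2414718	4.59e-05	0.128	0.025
48	rs1051168	1.27e-04	0.203	0.033
49	rs1078163	2.67e-05	0.095	0.017
50	rs2304634	7.90e-05	0.161	0.026
51	rs12708772	3.12e-03	0.662	0.044
52	rs4785714	1.34e-03	0.527	0.034
53	rs12966547	6.23e-06	0.071	0.019
54	rs159788	1.23e-03	0.527	0.034
55	rs381523	1.55e-03	0.560	0.038
56	rs9621795	1.66e-05	0.084	0.041
57	rs5758209	5.06e-06	0.068	0.031
58	rs28729663	1.82e-04	0.257	0.041
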