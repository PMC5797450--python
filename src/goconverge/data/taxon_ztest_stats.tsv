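criterion	taxon	Z	p	q
Actin	G_aurea	0.25	0.403	0.626
AltOx	G_aurea	0.75	0.228	0.416
AspPep	G_aurea	-0.74	0.771	0.674
ATP	G_aurea	-1.50	0.933	0.697
ATP_ADP	G_aurea	1.52	0.064	0.238
BGal	G_aurea	1.92	0.028	0.172
Chit	G_aurea	-0.35	0.637	0.674
CinAlc	G_aurea	1.22	0.111	0.345
CystPep	G_aurea	-1.15	0.876	0.697
FrucBPA	G_aurea	1.56	0.059	0.238
GlutTrans	G_aurea	-0.19	0.577	0.674
H2OChan	G_aurea	0.74	0.229	0.416
HeatShock	G_aurea	0.69	0.244	0.416
Lipase	G_aurea	-0.26	0.602	0.674
LipTrans	G_aurea	0.69	0.245	0.416
NHTrans	G_aurea	-0.82	0.794	0.674
Perox	G_aurea	-0.59	0.722	0.674
Phoslip	G_aurea	2.76	2.89E-03	0.054
Phosp	G_aurea	-1.35	0.912	0.697
Polygal	G_aurea	-0.46	0.678	0.674
ProtHomo	G_aurea	2.09	0.018	0.169
RiboNuc	G_aurea	-0.62	0.734	0.674
SerCarPep	G_aurea	-0.32	0.626	0.674
ThioGluc	G_aurea	0.85	0.198	0.416
Total	G_aurea	-0.38	0.649	0.674
Actin	D_capensis	-0.69	0.755	0.861
AltOx	D_capensis	3.72	1.01E-04	2.45E-03
AspPep	D_capensis	0.20	0.421	0.861
ATP	D_capensis	-1.22	0.889	0.861
ATP_ADP	D_capensis	1.71	0.043	0.523
BGal	D_capensis	0.55	0.291	0.861
Chit	D_capensis	-1.19	0.884	0.861
CinAlc	D_capensis	-0.39	0.650	0.861
CystPep	D_capensis	-0.55	0.708	0.861
FrucBPA	D_capensis	-0.64	0.739	0.861
GlutTrans	D_capensis	-0.20	0.578	0.861
H2OChan	D_capensis	0.65	0.259	0.861
HeatShock	D_capensis	-0.74	0.771	0.861
Lipase	D_capensis	-0.02	0.508	0.861
LipTrans	D_capensis	0.41	0.340	0.861
NHTrans	D_capensis	0.98	0.163	0.861
Perox	D_capensis	-0.24	0.596	0.861
Phoslip	D_capensis	0.31	0.379	0.861
Phosp	D_capensis	0.69	0.244	0.861
Polygal	D_capensis	-1.13	0.870	0.861
ProtHomo	D_capensis	0.11	0.458	0.861
RiboNuc	D_capensis	-0.42	0.661	0.861
SerCarPep	D_capensis	-0.92	0.821	0.861
ThioGluc	D_capensis	-0.41	0.658	0.861
Total	D_capensis	-0.56	0.711	0.861
Actin	U_gibba	-0.06	0.525	0.351
AltOx	U_gibba	2.36	9.17E-03	0.025
AspPep	U_gibba	1.75	0.040	0.060
ATP	U_gibba	3.19	7.19E-04	4.31E-03
ATP_ADP	U_gibba	1.54	0.062	0.083
BGal	U_gibba	0.55	0.291	0.296
Chit	U_gibba	-0.70	0.757	0.392
CinAlc	U_gibba	0.31	0.379	0.311
CystPep	U_gibba	2.00	0.023	0.046
FrucBPA	U_gibba	0.75	0.227	0.273
GlutTrans	U_gibba	-0.90	0.817	0.392
H2OChan	U_gibba	0.48	0.314	0.296
HeatShock	U_gibba	-0.07	0.527	0.351
Lipase	U_gibba	-0.35	0.637	0.376
LipTrans	U_gibba	-0.65	0.741	0.392
NHTrans	U_gibba	3.58	1.74E-04	2.09E-03
Perox	U_gibba	0.00	0.499	0.351
Phoslip	U_gibba	2.30	0.011	0.025
Phosp	U_gibba	2.65	4.05E-03	0.016
Polygal	U_gibba	0.47	0.320	0.296
ProtHomo	U_gibba	0.28	0.388	0.311
RiboNuc	U_gibba	-0.34	0.635	0.376
SerCarPep	U_gibba	-0.87	0.808	0.392
ThioGluc	U_gibba	-0.41	0.658	0.376
Total	U_gibba	1.79	0.036	0.060
Actin	C_follicularis	1.04	0.150	0.214
AltOx	C_follicularis	2.36	9.10E-03	0.030
AspPep	C_follicularis	-1.17	0.880	0.544
ATP	C_follicularis	-1.67	0.952	0.544
ATP_ADP	C_follicularis	1.91	0.028	0.050
BGal	C_follicularis	4.19	1.40E-05	1.99E-04
Chit	C_follicularis	-1.03	0.847	0.544
CinAlc	C_follicularis	-0.29	0.616	0.482
CystPep	C_follicularis	-1.43	0.923	0.544
FrucBPA	C_follicularis	-0.02	0.508	0.454
GlutTrans	C_follicularis	2.22	0.013	0.031
H2OChan	C_follicularis	3.08	1.04E-03	4.96E-03
HeatShock	C_follicularis	0.83	0.204	0.224
Lipase	C_follicularis	2.14	0.016	0.033
LipTrans	C_follicularis	2.31	0.010	0.030
NHTrans	C_follicularis	-0.86	0.806	0.544
Perox	C_follicularis	0.57	0.284	0.270
Phoslip	C_follicularis	3.50	2.28E-04	0.002
Phosp	C_follicularis	0.83	0.203	0.224
Polygal	C_follicularis	-0.45	0.674	0.482
ProtHomo	C_follicularis	0.62	0.269	0.270
RiboNuc	C_follicularis	-0.43	0.668	0.482
SerCarPep	C_follicularis	1.35	0.089	0.142
ThioGluc	C_follicularis	-0.41	0.658	0.482
Total	C_follicularis	0.86	0.195	0.224
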