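criterion	t	p	q
Actin	0.24	0.407	0.218
AltOx	3.14	0.011	0.047
AspPep	0.01	0.496	0.241
ATP	-0.24	0.590	0.241
ATP_ADP	4.00	4.30E-03	0.037
BGal	1.90	0.062	0.127
Chit	-1.82	0.944	0.324
CinAlc	0.39	0.355	0.218
CystPep	-0.32	0.619	0.241
FrucBPA	0.66	0.266	0.217
GlutTrans	0.29	0.391	0.218
H2OChan	1.68	0.074	0.127
HeatShock	0.32	0.377	0.218
Lipase	0.53	0.309	0.218
LipTrans	0.94	0.193	0.217
NHTrans	0.64	0.278	0.217
Perox	-0.14	0.552	0.241
Phoslip	2.79	0.019	0.053
Phosp	0.77	0.240	0.217
Polygal	-0.75	0.763	0.284
ProtHomo	1.27	0.122	0.174
RiboNuc	-1.10	0.841	0.300
SerCarPep	-0.29	0.608	0.241
ThioGluc	-0.18	0.570	0.241
Total	0.62	0.278	0.217
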