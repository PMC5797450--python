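label	abbreviation	codes
actin filament	Actin	GO:0005884
alpha-galactosidase activity	AGal	GO:0004557
alternative oxidase activity	AltOx	GO:0009916
ammonium transmembrane transport	NHTrans	GO:0008519;GO:0072488
aspartic-type endopeptidase activity	AspPep	GO:0004190
ATP:ADP antiporter activity	ATP_ADP	GO:0005471
ATPase activity	ATP	GO:0016887
beta-galactosidase activity	BGal	GO:0004565
beta-glucanase activity	BGluc	GO:0052736
chitinase activity	Chit	GO:0004568
cinnamyl-alcohol dehydrogenase activity	CinAlc	GO:0045551
cyclic-nucleotide phosphodiesterase activity	CycNucPDE	GO:0004112
cysteine-type peptidase activity	CystPep	GO:0008234
endonuclease complex	EndoNuc	GO:1905348
formate dehydrogenase complex	FormDH	GO:0009326
fructose-bisphosphate aldolase activity	FrucBPA	GO:0004332
glucosidase complex	Glucosid	GO:1902687
glutathione transferase activity	GlutTrans	GO:0004364
heat shock protein activity	HeatShock	GO:0042026;GO:0006986;GO:0034620
lipase activity	Lipase	GO:0016298
lipid transport	LipTrans	GO:0006869
methylammonium channel activity	MeNHChan	GO:0015264
peroxidase activity	Perox	GO:0004601
phosphatase activity	Phosp	GO:0016791
phospholipase activity	Phoslip	GO:0004620
polygalacturonase activity	Polygal	GO:0004650
polygalacturonase inhibitor activity	PolygalInh	GO:0090353
protein homodimerization activity	ProtHomo	GO:0042803
ribonuclease activity	RiboNuc	GO:0004540
serine-type carboxypeptidase activity	SerCarPep	GO:0004185
sodium ion transmembrane transporter activity	NaTrans	GO:0022816
superoxide dismutase activity	SOD	GO:0004784
symplast	Sympl	GO:0055044
thioglucosidase activity	ThioGluc	GO:0019137
water channel activity	H2OChan	GO:0015250
xylanase activity	Xylan	GO:0097599
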