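# Default nitrogen-cycle gene catalog.
# Columns: gene_symbol  ko_id  complex_id  subunit_role  process
# Edit this file (or pass your own via load_catalog) to revise KO assignments;
# all pipeline logic keys on gene_symbol.
gene_symbol	ko_id	complex_id	subunit_role	process
rpsB	K02967	RpsB	ribosomal protein S2, universal single-copy marker	marker
nifH	K02588	Nif	[FeMo]-nitrogenase iron protein	nitrogen_fixation
nifD	K02586	Nif	[FeMo]-nitrogenase alpha subunit	nitrogen_fixation
nifK	K02591	Nif	[FeMo]-nitrogenase beta subunit	nitrogen_fixation
vnf	K22896	Vnf	[FeV]-nitrogenase alpha subunit	nitrogen_fixation
anf	K22899	Anf	[FeFe]-nitrogenase alpha subunit	nitrogen_fixation
amoA	K10944	Amo	ammonia monooxygenase subunit A	nitrification
amoB	K10945	Amo	ammonia monooxygenase subunit B	nitrification
amoC	K10946	Amo	ammonia monooxygenase subunit C	nitrification
hao	K10535	Hao	hydroxylamine dehydrogenase	nitrification
narG	K00370	NarGHI	membrane-bound nitrate reductase alpha (catalytic; shared KO with nxrA)	denitrification
narH	K00371	NarGHI	membrane-bound nitrate reductase beta (shared KO with nxrB)	denitrification
narI	K00374	NarGHI	membrane-bound nitrate reductase gamma (membrane anchor)	denitrification
napA	K02567	NapAB	periplasmic nitrate reductase catalytic subunit	denitrification
napB	K02568	NapAB	periplasmic nitrate reductase cytochrome c subunit	denitrification
nirK	K00368	NirK	copper-containing nitrite reductase (NO-forming)	denitrification
nirS	K15864	NirS	cytochrome cd1 nitrite reductase (NO-forming)	denitrification
norB	K04561	NorBC	nitric oxide reductase catalytic subunit	denitrification
norC	K02305	NorBC	nitric oxide reductase cytochrome c subunit	denitrification
nosZ	K00376	NosZ	nitrous oxide reductase	denitrification
nirB	K00362	NirBD	NADH-dependent nitrite reductase catalytic subunit	dissimilatory_nitrate_reduction
nirD	K00363	NirBD	NADH-dependent nitrite reductase small subunit	dissimilatory_nitrate_reduction
nrfA	K03385	Nrf	cytochrome c-552 ammonia-forming nitrite reductase	dissimilatory_nitrate_reduction
nrfH	K15876	Nrf	cytochrome c quinol dehydrogenase (Nrf electron donor)	dissimilatory_nitrate_reduction
nasA	K00372	Nas	assimilatory nitrate reductase catalytic subunit	assimilatory_nitrate_reduction
nasB	K00360	Nas	assimilatory nitrate reductase electron-transfer subunit	assimilatory_nitrate_reduction
nirA	K00366	NirA	ferredoxin-nitrite reductase (assimilatory)	assimilatory_nitrate_reduction
hzs	K20932	Hzs	hydrazine synthase	anammox
hdh	K20935	Hdh	hydrazine dehydrogenase	anammox
ureA	K01430	Ure	urease gamma subunit	ammonification
ureB	K01429	Ure	urease beta subunit	ammonification
ureC	K01428	Ure	urease alpha subunit	ammonification
cynS	K01725	CynS	cyanase	ammonification
NIT1	K01501	NIT1	nitrilase	ammonification
glnA	K01915	GlnA	glutamine synthetase	organic_nitrogen_utilization
gltB	K00265	GltBD	glutamate synthase large subunit	organic_nitrogen_utilization
gltD	K00266	GltBD	glutamate synthase small subunit	organic_nitrogen_utilization
gdhA	K00262	GdhA	glutamate dehydrogenase (NADP+)	organic_nitrogen_utilization
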