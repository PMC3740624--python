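code	name	alt_names	combining	formula	fragment
ala	alanine		alanyl	C3H7NO2	NC(C)C(=O)
arg	arginine		arginyl	C6H14N4O2	NC(CCCNC(N)=N)C(=O)
asn	asparagine		asparaginyl	C4H8N2O3	NC(CC(N)=O)C(=O)
asp	aspartic acid	aspartate	aspartyl	C4H7NO4	NC(CC(O)=O)C(=O)
cys	cysteine		cysteinyl	C3H7NO2S	NC(CS)C(=O)
gln	glutamine		glutaminyl	C5H10N2O3	NC(CCC(N)=O)C(=O)
glu	glutamic acid	glutamate	glutamyl	C5H9NO4	NC(CCC(O)=O)C(=O)
gly	glycine		glycyl	C2H5NO2	NCC(=O)
his	histidine		histidyl|histidinyl	C6H9N3O2	NC(Cc1c[nH]cn1)C(=O)
ile	isoleucine		isoleucyl	C6H13NO2	NC(C(C)CC)C(=O)
leu	leucine		leucyl	C6H13NO2	NC(CC(C)C)C(=O)
lys	lysine		lysyl	C6H14N2O2	NC(CCCCN)C(=O)
met	methionine		methionyl	C5H11NO2S	NC(CCSC)C(=O)
phe	phenylalanine		phenylalanyl	C9H11NO2	NC(Cc1ccccc1)C(=O)
pro	proline		prolyl	C5H9NO2	N1CCCC1C(=O)
ser	serine		seryl	C3H7NO3	NC(CO)C(=O)
thr	threonine		threonyl	C4H9NO3	NC(C(O)C)C(=O)
trp	tryptophan		tryptophyl|tryptophanyl	C11H12N2O2	NC(Cc1c[nH]c2ccccc12)C(=O)
tyr	tyrosine		tyrosyl	C9H11NO3	NC(Cc1ccc(O)cc1)C(=O)
val	valine		valyl	C5H11NO2	NC(C(C)C)C(=O)
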