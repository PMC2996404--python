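# coordinate	family
chr1:20206-20395(-)	MER53
chr2:114056977-114057166(+)	MER53
chr2:207842230-207842416(-)	MER53
chr7:18133317-18133525(-)	MER53
chr8:142865462-142865600(+)	MER53
chr9:20121-20310(-)	MER53
chr9:99165632-99165820(-)	MER53
chr12:111617205-111617395(-)	MER53
chr15:100318156-100318345(+)	MER53
chr19:22950-23139(-)	MER53
chr20:48664721-48665024(+)	AluSx1
chr20:48664577-48664719(+)	MER53
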