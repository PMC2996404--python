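# coordinate	name
chr1:20229-20366(+)	miR1302-2
chr2:114057006-114057143(-)	miR1302-3
chr2:207842244-207842393(-)	miR1302-4
chr7:18133368-18133457(-)	miR1302-6
chr8:142865510-142865581(-)	miR1302-7
chr9:20144-20281(+)	miR1302-2
chr9:99165657-99165784(-)	miR1302-8
chr12:111617222-111617364(-)	miR1302-1
chr15:100318185-100318322(-)	miR1302-2
chr19:22973-23110(+)	miR1302-2
chr20:48664580-48664729(-)	miR1302-5
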