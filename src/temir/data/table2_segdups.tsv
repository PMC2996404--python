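# pair_id	sd1	sd2	mirnas_in_sd1	mirnas_in_sd2
1	chr1:466-30596(-)	chr2:114046769-114076456(-)	miR1302-2(chr1)	miR1302-3(chr2)
2	chr1:487-76975(-)	chr15:100263880-100338121(-)	miR1302-2(chr1)	miR1302-2(chr15)
3	chr1:487-30596(+)	chr9:845-30515(+)	miR1302-2(chr1)	miR1302-2(chr9)
4	chr1:8257-76975(+)	chr19:11002-79672(+)	miR1302-2(chr1)	miR1302-2(chr19)
5	chr2:113887481-114076781(-)	chr9:413-193762(-)	miR1302-3(chr2)	miR1302-2(chr9)
6	chr2:114046769-114069083(-)	chr19:11002-33344(+)	miR1302-3(chr2)	miR1302-2(chr19)
7	chr2:114046769-114076720(+)	chr15:100307957-100338402(+)	miR1302-3(chr2)	miR1302-2(chr15)
8	chr9:437-30515(-)	chr15:100307957-100338529(-)	miR1302-2(chr9)	miR1302-2(chr15)
9	chr9:8507-30515(+)	chr19:11002-33344(+)	miR1302-2(chr9)	miR1302-2(chr19)
10	chr15:100218756-100330295(-)	chr19:11002-123445(-)	miR1302-2(chr15)	miR1302-2(chr19)
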