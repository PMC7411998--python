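id	name	formula	topology	n_oh	structure	status
1	speibonoxamine	C27H50N6O6	linear	0	Ac|cad|succ|cad|succ|cad|Ac	isolated
2	desoxy-desferrioxamine D1	C27H50N6O8	linear	2	Ac|cad|succ|cad(OH)|succ|cad(OH)|Ac	isolated
3	desferrioxamine D1	C27H50N6O9	linear	3	Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)|Ac	isolated
4	desferrioxamine B	C25H48N6O8	linear	3	Ac|cad(OH)|succ|cad(OH)|succ|cad(OH)	isolated
5	desoxynocardamine	C27H48N6O8	cyclic	2	cyclo[cad|succ|cad(OH)|succ|cad(OH)|succ]	isolated
6	nocardamine	C27H48N6O9	cyclic	3	cyclo[cad(OH)|succ|cad(OH)|succ|cad(OH)|succ]	isolated
7	hexahydro-3-((4-hydroxyphenyl)methyl)-pyrrolo[1,2-a]pyrazine-1,4-dione	C14H16N2O3	other	0		isolated
8	didesoxy-desferrioxamine D1	C27H50N6O7	linear	1	Ac|cad|succ|cad|succ|cad(OH)|Ac	network_proposed
9	desoxy-desferrioxamine B	C25H48N6O7	linear	2	Ac|cad(OH)|succ|cad(OH)|succ|cad	network_proposed
10	didesoxy-desferrioxamine B	C25H48N6O6	linear	1	Ac|cad(OH)|succ|cad|succ|cad	network_proposed
12	ferrioxamine B	C25H45FeN6O8	other	3		network_identified
13	ferrioxamine E	C27H45FeN6O9	other	3		network_identified
14	ferrioxamine D1	C27H47FeN6O9	other	3		network_identified
16	hexahydro-3-(phenylmethyl)-pyrrolo[1,2-a]pyrazine-1,4-dione	C14H16N2O2	other	0		network_identified
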