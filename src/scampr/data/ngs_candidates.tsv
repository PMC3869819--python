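position	ref	alt	pools	plate	wells
475	C	T	2,7,12	4	E4,E5,E6,F4,F5,F6
701	C	T	2,8,12	4	G4,G5,G6,H4,H5,H6
803	G	A	1,7,9	1	E1,E2,E3,F1,F2,F3
1017	G	A	1,7,10	2	E1,E2,E3,F1,F2,F3
1044	G	A	1,5,11	3	A1,A2,A3,B1,B2,B3
1089	G	A	4,7,12	4	E10,E11,E12,F10,F11,F12
1288	C	T	4,7,10	2	E10,E11,E12,F10,F11,F12
1399	G	A	2,8,11	3	G4,G5,G6,H4,H5,H6
1454	G	A	2,6,12	4	C4,C5,C6,D4,D5,D6
1477	G	A	3,8,11	3	A7,A8,A9,B7,B8,B9
1506	G	A	2,6,11	3	C4,C5,C6,D4,D5,D6
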