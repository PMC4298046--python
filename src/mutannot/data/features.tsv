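protein_id	mutation	spread	ss	rsa	rsa_bold_buried	interaction	domain	natural_variant	note
P41250	Ala111Val	A:77,S:21,E:1,-:1	NA	NA	0			0	no corresponding residue in the crystal structure
P41250	Glu125Gly	E:84,-:10,D:6	H	22.7	0			0
P41250	Pro152Leu	P:99,-:1	H	75.0	0	Dimerization		0
P41250	Leu183Pro	L:90,-:8,M:1,V:1	E	54.3	0	Dimerization	Catalytic	0
P41250	Cys211Arg	C:100	E	34.8	0	Dimerization	Catalytic	0
P41250	Pro288Lys	P:98,-:2	S	94.1	0	Dimerization	Catalytic	0
P41250	Gly294Arg	G:81,-:16,P:1,K:1,T:1	E	0.0	1		Catalytic	0
P41250	Pro298Leu	P:97,-:3	S	0.7	1		Catalytic	0
P41250	Ile334Phe	I:81,-:8,L:8,V:2,C:1	S	11.2	1	Dimerization	Catalytic	0
P41250	His472Arg	H:80,-:20	H	3.3	1			0
P41250	Asp554Asn	D:81,-:8,K:7,G:2,N:1,S:1	NA	NA	0			1	mutant residue natural in GRS of C. cristata; disordered region of the structure
P41250	Gly580Arg	G:92,-:8	E	14.3	1			0
P41250	Ser635Leu	S:83,-:8,T:7,A:2	H	24.6	0		C-terminal	0
P41250	Gly652Ala	G:85,H:8,-:7	S	46.4	0		C-terminal	0
Q9P2J5	Lys82Arg	K:81,-:18,N:1	-	22.4	0		Catalytic	0
Q9P2J5	Tyr373Cys	Y:100	E	21.3	0		Catalytic	0
P54577	Gly41Arg	G:74,-:26	E	40.4	0	ATP/amino-acid binding	Catalytic	0
P54577	Glu196Lys	E:74,-:25,P:1	H	16.9	1		Catalytic	0
P49588	Asn71Tyr	N:97,-:3	E	0.0	1		Catalytic	0
P49588	Arg329His	R:98,-:2	H	4.3	1		Catalytic	0
P49588	Glu778Ala	E:79,T:10,A:6,G:2,S:2,V:1	NA	NA	0			1	mutant residue natural in B. taurus ARS
P49588	Asp893Asn	D:75,P:21,N:2,X:1,-:1	NA	NA	0			1	mutant residue natural in ferret ARS
Q15046	Leu133His	L:100	H	2.4	1		Anti-codon binding	0
Q15046	Ile302Met	I:100	S	29.5	0		Catalytic	0
Q15046	Thr623Ser	T:77,P:16,-:4,A:1,M:1,V:1	NA	NA	0			0	no corresponding residue in structural homologues
Q15031	His324Gln	H:48,K:22,C:14,-:4,R:4,N:3,P:3,A:1,G:1	H	4.7	1		Catalytic	0
Q15031	Thr522Asn	T:86,-:14	T	20.4	0		Catalytic	0	printed plain yet categorised as buried structural core; recorded, not resolved
Q15031	Thr629Met	T:63,L:22,-:14,V:1	E	11.6	1		Catalytic	0
Q5JPH6	Arg55His	R:77,K:12,-:10,L:1	H	4.4	1		Catalytic	0
Q5JPH6	Glu96Lys	E:79,A:10,-:8,T:3	H	64.9	0		Catalytic	0
Q5JPH6	Arg107His	R:79,-:15,H:2,T:2,C:1,Q:1	T	47.8	0		Catalytic	1	mutant residue natural in mitochondrial ERS of M. davidii
Q5JPH6	Arg108Trp	R:78,-:15,Q:4,E:3	T	56.8	0		Catalytic	0
Q5JPH6	Gly110Ser	G:84,-:15,E:1	-	52.8	0		Catalytic	0
Q5JPH6	Cys167Tyr	C:83,-:15,Q:1,R:1	-	-	0		Catalytic	0
Q5JPH6	Arg168Gly	R:83,-:14,L:2,K:1	-	-	0		Catalytic	0
Q5JPH6	Gly204Ser	G:82,Y:11,-:6,V:1	E	38.1	0		Catalytic	0
Q5JPH6	Gly224Ser	G:81,-:17,A:1,V:1	S	42.8	0		Catalytic	0
Q5JPH6	Gly317Cys	G:81,T:10,-:7,S:2	-	44.7	0	tRNA binding	Catalytic	0
Q5JPH6	Arg516Gln	R:71,-:11,D:10,S:3,E:2,K:2,V:1	H	6.4	1		C-terminal	0
Q9Y2Z4	Gly46Asp	G:84,-:12,Q:2,E:1,S:1	T	52.3	0			0
Q9Y2Z4	Phe52Leu	F:89,-:10,Y:1	E	28.8	0			0
Q5T160	Ile9Val	I:84,-:12,A:1,E:1,F:1,L:1	-	-	0			0	structural disorder in homologues
Q5T160	Gln12Arg	Q:53,E:25,-:11,K:6,T:3,L:1,R:1	-	-	0			1	mutant residue natural in rabbit RRS; structural disorder in homologues
Q5T160	Trp241Arg	W:98,-:2	H	13.2	1		Catalytic	0
Q5T160	Arg245Gln	R:98,-:2	H	6.8	1		Catalytic	0
Q5T160	Arg469His	R:99,-:1	H	23.4	0	tRNA binding	Editing	0
Q9NP81	Asp390Gly	D:78,N:14,-:7,E:1	E	1.2	1		Catalytic	0
Q9NP81	Arg402His	R:78,K:14,-:7,A:1	E	14.9	1		Catalytic	0
P49590	Leu200Val	L:100	H	0.0	1		Catalytic	0
P49590	Val368Leu	V:100	H	1.2	1		Catalytic	0
O95363	Tyr144Cys	Y:73,-:19,F:6,E:1,L:1	-	0.9	1		Catalytic	0
O95363	Ile329Thr	I:73,-:16,W:6,L:3,G:1,V:1	G	4.1	1		Catalytic	0
O95363	Asp391Val	D:81,-:16,G:2,E:1	G	26.3	0			0
Q5JTZ9	Leu155Arg	L:97,-:3	H	0.0	1		Catalytic	0
Q5JTZ9	Arg592Trp	R:51,Q:20,N:20,G:6,-:3	-	-	0		Catalytic	0
Q6PI48	Ser45Gly	S:76,-:14,N:8,E:1,K:1	S	10.7	1	Dimerization		0
Q6PI48	Cys152Phe	C:74,A:16,-:6,Q:1,S:1,W:1,X:1	-	31.1	0	Dimerization		0
Q6PI48	Arg179His	R:92,-:7,G:1	T	28.6	0		Catalytic	0
Q6PI48	Leu239Pro	L:93,-:7	-	18.2	1		Catalytic	0
Q6PI48	Arg263Gln	R:79,P:16,-:5	E	56.0	0	Dimerization	Catalytic	0
Q6PI48	Leu613Phe	L:74,P:15,-:11	S	41.4	0	tRNA binding		0
Q6PI48	Leu626Gln	L:73,-:25,I:2	T	64.0	0			0
Q6PI48	Leu626Val	L:73,-:25,I:2	T	64.0	0			0
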