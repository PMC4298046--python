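protein_id	enzyme	compartment	aars_class	oligomer	mutation	disease	note
P41250	GRS	cytoplasmic	II	Dimer	Ala111Val	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Glu125Gly	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Pro152Leu	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Leu183Pro	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Cys211Arg	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Pro288Lys	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Gly294Arg	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Pro298Leu	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)	absent from the mutation-list table but present in the feature table and the 14-mutation census; retained
P41250	GRS	cytoplasmic	II	Dimer	Ile334Phe	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	His472Arg	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Asp554Asn	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Gly580Arg	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Ser635Leu	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
P41250	GRS	cytoplasmic	II	Dimer	Gly652Ala	Distal hereditary motor neuropathy (dHMN) or distal spinal muscular atrophy (dSMA)
Q9P2J5	LRS	cytoplasmic	I	Monomer	Lys82Arg	Infantile hepatopathy
Q9P2J5	LRS	cytoplasmic	I	Monomer	Tyr373Cys	Infantile hepatopathy
P54577	YRS	cytoplasmic	I	Dimer	Gly41Arg	Dominant intermediate Charcot-Marie-Tooth disorder type C (DI-CMTC)
P54577	YRS	cytoplasmic	I	Dimer	Glu196Lys	Dominant intermediate Charcot-Marie-Tooth disorder type C (DI-CMTC)
P54577	YRS	cytoplasmic	I	Dimer	Val153-Val156	Dominant intermediate Charcot-Marie-Tooth disorder type C (DI-CMTC)	four-residue deletion in helix H7 of the Rossmann fold
P49588	ARS	cytoplasmic	II	Monomer	Asn71Tyr	dHMN, CMT type 2N
P49588	ARS	cytoplasmic	II	Monomer	Arg329His	dHMN, CMT type 2N
P49588	ARS	cytoplasmic	II	Monomer	Glu778Ala	dHMN, CMT type 2N
P49588	ARS	cytoplasmic	II	Monomer	Asp893Asn	dHMN, CMT type 2N
Q15046	KRS	cytoplasmic	II	Dimer	Leu133His	CMT
Q15046	KRS	cytoplasmic	II	Dimer	Ile302Met	CMT
Q15046	KRS	cytoplasmic	II	Dimer	Thr623Ser	CMT
Q15046	KRS	cytoplasmic	II	Dimer	Tyr173SerfsX7	CMT	frameshift in the anticodon-binding domain; premature termination
Q15031	LRS	mitochondrial	I	Monomer	His324Gln	Type-2 diabetes, Perrault syndrome
Q15031	LRS	mitochondrial	I	Monomer	Thr522Asn	Type-2 diabetes, Perrault syndrome
Q15031	LRS	mitochondrial	I	Monomer	Thr629Met	Type-2 diabetes, Perrault syndrome
Q5JPH6	ERS	mitochondrial	I	Monomer	Arg55His	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Glu96Lys	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Arg107His	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Arg108Trp	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Gly110Ser	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Cys167Tyr	Leukoencephalopathy LTBL	mutation-list table prints Lys167Tyr; the feature table reads Cys167Tyr, which is used here
Q5JPH6	ERS	mitochondrial	I	Monomer	Arg168Gly	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Gly204Ser	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Gly224Ser	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Gly317Cys	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Arg516Gln	Leukoencephalopathy LTBL
Q5JPH6	ERS	mitochondrial	I	Monomer	Thr426_Arg427insL	Leukoencephalopathy LTBL	insertion mutation
Q9Y2Z4	YRS	mitochondrial	I	Dimer	Gly46Asp	Myopathy, lactic acidosis, and sideroblastic anemia (MLASA)
Q9Y2Z4	YRS	mitochondrial	I	Dimer	Phe52Leu	Myopathy, lactic acidosis, and sideroblastic anemia (MLASA)
Q5T160	RRS	mitochondrial	I	Monomer	Ile9Val	Ponto cerebellar hypoplasia type 6 (PCH6)
Q5T160	RRS	mitochondrial	I	Monomer	Gln12Arg	Ponto cerebellar hypoplasia type 6 (PCH6)
Q5T160	RRS	mitochondrial	I	Monomer	Trp241Arg	Ponto cerebellar hypoplasia type 6 (PCH6)	feature table prints Trp421Arg; the running text and category table read Trp241Arg, which is used here
Q5T160	RRS	mitochondrial	I	Monomer	Arg245Gln	Ponto cerebellar hypoplasia type 6 (PCH6)
Q5T160	RRS	mitochondrial	I	Monomer	Arg469His	Ponto cerebellar hypoplasia type 6 (PCH6)
Q9NP81	SRS	mitochondrial	II	Dimer	Asp390Gly	HUPRA syndrome
Q9NP81	SRS	mitochondrial	II	Dimer	Arg402His	HUPRA syndrome
P49590	HRS	mitochondrial	II	Dimer	Leu200Val	Perrault syndrome, ovarian dysgenesis and sensorineural hearing loss
P49590	HRS	mitochondrial	II	Dimer	Val368Leu	Perrault syndrome, ovarian dysgenesis and sensorineural hearing loss
P49590	HRS	mitochondrial	II	Dimer	Leu200-Lys211	Perrault syndrome, ovarian dysgenesis and sensorineural hearing loss	deletion spanning a turn and a strand at the dimer interface
O95363	FRS	mitochondrial	II	Dimer	Tyr144Cys	Fatal infantile Alpers encephalopathy, mitochondrial myopathies
O95363	FRS	mitochondrial	II	Dimer	Ile329Thr	Fatal infantile Alpers encephalopathy, mitochondrial myopathies
O95363	FRS	mitochondrial	II	Dimer	Asp391Val	Fatal infantile Alpers encephalopathy, mitochondrial myopathies
Q5JTZ9	ARS	mitochondrial	II	Monomer	Leu155Arg	Infantile cardiomyopathies
Q5JTZ9	ARS	mitochondrial	II	Monomer	Arg592Trp	Infantile cardiomyopathies
Q6PI48	DRS	mitochondrial	II	Dimer	Ser45Gly	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Cys152Phe	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Arg179His	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Leu239Pro	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Arg263Gln	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Leu613Phe	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Leu626Gln	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Leu626Val	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)
Q6PI48	DRS	mitochondrial	II	Dimer	Met134-Lys165	Leukoencephalopathy with brainstem and spinal cord involvement and elevated lactate (LBSL)	deletion within the anticodon-binding domain
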