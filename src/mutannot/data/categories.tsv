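protein_id	mutation	disease_group	prior_annotation	feature_label	letter
P41250	Ala111Val	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Un-annotated	D
P41250	Glu125Gly	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Dimerization	C
P41250	Pro152Leu	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Dimerization	C
P41250	Leu183Pro	Charcot-Marie-Tooth disorder (CMT)	Defective dimerization	Dimerization	C
P41250	Cys211Arg	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Structural stability	B
P41250	Pro288Lys	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Dimerization	C
P41250	Gly294Arg	Charcot-Marie-Tooth disorder (CMT)	Defective dimerization	Structural stability	B
P41250	Pro298Leu	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Structural stability	B
P41250	Ile334Phe	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Dimerization	C
P41250	His472Arg	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Structural stability	B
P41250	Asp554Asn	Charcot-Marie-Tooth disorder (CMT)	Enhanced dimerization	Un-annotated	D
P41250	Gly580Arg	Charcot-Marie-Tooth disorder (CMT)	Enhanced dimerization	Structural stability	B
P41250	Ser635Leu	Charcot-Marie-Tooth disorder (CMT)	Enhanced dimerization	Inter-molecular interaction	C
P41250	Gly652Ala	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Inter-molecular interaction	C
P54577	Gly41Arg	Charcot-Marie-Tooth disorder (CMT)	Impaired tyrosine activation	ATP/amino-acid binding	A
P54577	Glu196Lys	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Structural stability	B
P49588	Asn71Tyr	Charcot-Marie-Tooth disorder (CMT)	Impaired tRNA charging	Structural stability	B
P49588	Arg329His	Charcot-Marie-Tooth disorder (CMT)	Impaired tRNA charging	Structural stability	B
P49588	Glu778Ala	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Un-annotated	D
P49588	Asp893Asn	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Un-annotated	D
Q15046	Leu133His	Charcot-Marie-Tooth disorder (CMT)	Decreased enzyme activity	Structural stability	B
Q15046	Ile302Met	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Inter-molecular interactions	C
Q15046	Thr623Ser	Charcot-Marie-Tooth disorder (CMT)	No reported annotation	Un-annotated	D
Q9P2J5	Lys82Arg	Infantile hepatopathy	No reported annotation	Un-annotated	D
Q9P2J5	Tyr373Cys	Infantile hepatopathy	No reported annotation	Structural stability	B
Q15031	His324Gln	Type-2 diabetes	No reported annotation	Structural stability	B
Q15031	Thr522Asn	Perrault syndrome, ovarian failure and hearing loss	Decreased enzyme activity	Structural stability	B
Q15031	Thr629Met	Perrault syndrome, ovarian failure and hearing loss	No reported annotation	Structural stability	B
P49590	Leu200Val	Perrault syndrome, ovarian failure and hearing loss	Decreased enzyme activity	Structural stability	B
P49590	Val368Leu	Perrault syndrome, ovarian failure and hearing loss	Decreased enzyme activity	Structural stability	B
Q9Y2Z4	Gly46Asp	Myopathy, lactic acidosis, and sideroblastic anemia (MLASA)	Translational defects	Inter-molecular interactions	C
Q9Y2Z4	Phe52Leu	Myopathy, lactic acidosis, and sideroblastic anemia (MLASA)	Abnormal enzyme kinetics	Inter-molecular interactions	C
Q9NP81	Asp390Gly	HUPRA syndrome	Decreased enzyme activity	Structural stability	B
Q9NP81	Arg402His	HUPRA syndrome	No reported annotation	Structural stability	B
Q5JTZ9	Leu155Arg	Infantile cardiomyopathies	No reported annotation	Un-annotated	D
Q5JTZ9	Arg592Trp	Infantile cardiomyopathies	No reported annotation	Un-annotated	D
Q5T160	Ile9Val	Ponto cerebellar hypoplasia	No reported annotation	Un-annotated	D
Q5T160	Gln12Arg	Ponto cerebellar hypoplasia	No reported annotation	Un-annotated	D
Q5T160	Trp241Arg	Ponto cerebellar hypoplasia	No reported annotation	Structural stability	B
Q5T160	Arg245Gln	Ponto cerebellar hypoplasia	No reported annotation	Structural stability	B
Q5T160	Arg469His	Ponto cerebellar hypoplasia	No reported annotation	tRNA binding	A
Q5JPH6	Arg55His	Leukoencephalopathy LBSL/LTBL	No reported annotation	Structural stability	B
Q5JPH6	Glu96Lys	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q5JPH6	Arg107His	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q5JPH6	Arg108Trp	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q5JPH6	Gly110Ser	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q5JPH6	Cys167Tyr	Leukoencephalopathy LBSL/LTBL	No reported annotation	Un-annotated	D
Q5JPH6	Arg168Gly	Leukoencephalopathy LBSL/LTBL	No reported annotation	Un-annotated	D
Q5JPH6	Gly204Ser	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q5JPH6	Gly224Ser	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q5JPH6	Gly317Cys	Leukoencephalopathy LBSL/LTBL	No reported annotation	tRNA binding	A
Q5JPH6	Arg516Gln	Leukoencephalopathy LBSL/LTBL	No reported annotation	Structural stability	B
Q6PI48	Ser45Gly	Leukoencephalopathy LBSL/LTBL	No reported annotation	Dimerization	C
Q6PI48	Cys152Phe	Leukoencephalopathy LBSL/LTBL	Defective dimerization	Dimerization	C
Q6PI48	Arg179His	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
Q6PI48	Leu239Pro	Leukoencephalopathy LBSL/LTBL	No reported annotation	Un-annotated	D
Q6PI48	Arg263Gln	Leukoencephalopathy LBSL/LTBL	Defective dimerization	Dimerization	C
Q6PI48	Leu613Phe	Leukoencephalopathy LBSL/LTBL	No reported annotation	tRNA binding	A
Q6PI48	Leu626Gln	Leukoencephalopathy LBSL/LTBL	Decreased enzyme activity	Inter-molecular interactions	C
Q6PI48	Leu626Val	Leukoencephalopathy LBSL/LTBL	No reported annotation	Inter-molecular interactions	C
O95363	Tyr144Cys	Fatal infantile Alpers encephalopathy, mitochondrial myopathies	Defective tRNA binding	Un-annotated	D
O95363	Ile329Thr	Fatal infantile Alpers encephalopathy, mitochondrial myopathies	Impaired stability/decreased ATP binding	Structural stability	B
O95363	Asp391Val	Fatal infantile Alpers encephalopathy, mitochondrial myopathies	Impaired stability/decreased Phe binding	Inter-molecular interactions	C
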