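59057067d6d5ae8f94258aaf8b4e6ab1c2e89a290e844fbcd912f50708d924d0  mutations.tsv
d0ec394f85c8cfcf61910d6998b4ef10ab09f3568c029c9f8cb6ea00517b6d6a  features.tsv
ef200a6b6b5f813adc8ead13087a0f600d5b89d7cf1cb860d35f23416a73138e  categories.tsv
38b3eb22b1c385be3962fbf653efc3158c44bd201f105b5a52b7ea12f593a73b  synthetic_P41250.fasta
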