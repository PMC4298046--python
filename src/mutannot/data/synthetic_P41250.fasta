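>P41250 synthetic stand-in GRS query sequence (correct wild-type residues at curated mutation sites; filler elsewhere)
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLANPQRSTVWY
ACDEEGHIKLMNPQRSTVWYACDEFGHIKLMPPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACLEFGHIKLMNPQRSTVWYACDEFGHIKLCNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHPKLMNPGRSTPWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPIRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMHPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPDRSTVWYACDEFGHIKLMNPQRSTVWGACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQSSTVWYACDEFGHIKLMGPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVW
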