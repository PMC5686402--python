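NCC(=O)O glycine
CC(N)C(=O)O alanine
CC(C)C(N)C(=O)O valine
CC(C)CC(N)C(=O)O leucine
CCC(C)C(N)C(=O)O isoleucine
OC(=O)C1CCCN1 proline
NC(CC1=CC=CC=C1)C(=O)O phenylalanine
NC(CC1=CNC2=CC=CC=C12)C(=O)O tryptophan
CSCCC(N)C(=O)O methionine
OCC(N)C(=O)O serine
CC(O)C(N)C(=O)O threonine
NC(CS)C(=O)O cysteine
NC(CC1=CC=C(O)C=C1)C(=O)O tyrosine
NC(=O)CC(N)C(=O)O asparagine
NC(=O)CCC(N)C(=O)O glutamine
OC(=O)CC(N)C(=O)O aspartate
OC(=O)CCC(N)C(=O)O glutamate
NCCCCC(N)C(=O)O lysine
NC(=N)NCCCC(N)C(=O)O arginine
NC(CC1=CNC=N1)C(=O)O histidine
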