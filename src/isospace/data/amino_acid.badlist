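# Chemical-plausibility badlist for amino-acid library generation.
# A reconstruction in the spirit of the forbidden-substructure lists
# used for published virtual amino-acid libraries (the original list
# is not reproduced here); each entry carries its rationale.
O~O        # peroxide: unstable O-O single/any bond
N~N~N      # azide-like N chains: explosive / unstable
OC[OH]     # hemiacetal / geminal diol: carbonyl-hydrate equilibrium species
OC(O)O     # orthoester: hydrolytically unstable
C=CO       # enol / enol ether: tautomer of the carbonyl form
C=C[NH]    # enamine with N-H: tautomer of the imine/carbonyl chemistry
N=CO       # imidate-like N=C-O: hydrolyzes to amide
[NH]C[OH]  # hemiaminal: carbinolamine equilibrium species
NC[NH2]    # aminal carbon: unstable N,N-acetal
O=C=O      # free or cumulated carbon dioxide motif
C=C=C      # allene/cumulene: high-energy, polymerizes
N=N        # azo linkage: photochemically/reductively labile
S~S        # disulfide-type S-S: redox-labile for a monomer library
[SH]C[OH]  # thiohemiacetal: equilibrium species
*1~*~*~1   # three-membered ring: prohibitive strain
*1~*~*~*~1 # four-membered ring: strained
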