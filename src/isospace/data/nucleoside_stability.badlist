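# Stability badlist for nucleoside-analogue enumeration.
# Forbidden substructures for monomers that must survive aqueous,
# moderate-pH/temperature conditions and covalent incorporation into a
# linear polymer.  One SMARTS-subset pattern per line; the comment is
# the chemical rationale.  "B" is the univalent recognition-moiety
# placeholder (e.g. a nucleobase).
#
# This list is a documented reconstruction in the spirit of published
# forbidden-substructure lists for this compound class, not a copy of
# any published list; the per-pattern sensitivity of the library size
# is reported by the sensitivity tooling.
O~O        # peroxide-type O-O bond: oxidatively/hydrolytically unstable
OB         # recognition moiety attached to oxygen: labile O-glycoside-like linkage; attachment must be at carbon
BC=O       # acyl attachment of the recognition moiety: activated carbonyl, hydrolyzes
OC[OH]     # hemiacetal / geminal-diol carbon: exists only in equilibrium with the open carbonyl form
OC(O)O     # orthoester carbon: rapidly hydrolyzed in water
C=CO       # enol or enol ether: tautomerizes / hydrolyzes under mild acid
[CH]=O     # free aldehyde: reactive electrophile (hydration, aldol, Schiff-base chemistry)
CC(=O)C    # ketone: reactive carbonyl under biochemical conditions
*1~*~*~1   # three-membered ring: prohibitive ring strain
*1~*~*~*~1 # four-membered ring: strained, prone to ring opening
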