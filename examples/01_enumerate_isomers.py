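"""Enumerate constitutional isomers of small molecular formulae.

Every connected molecule satisfying fixed valences (C4, N3, O2, S2,
H1) is generated exactly once; the count is the size of the formula's
constitutional-isomer space.
"""

from isospace import count_isomers, enumerate_isomers, parse_formula, to_smiles

for text in ["C2H6O", "C2H4O", "C4H10", "C6H6"]:
    print(f"{text}: {count_isomers(parse_formula(text))} constitutional isomers")

print("\nThe three C2H4O isomers (oxirane, acetaldehyde, vinyl alcohol):")
for mol in enumerate_isomers(parse_formula("C2H4O")):
    print(" ", to_smiles(mol))
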