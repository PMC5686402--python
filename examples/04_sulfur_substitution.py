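"""Symmetry-aware O -> S substitution versus de novo generation.

Because O and S share a valence, S-containing isomers can be derived
from an O-containing library by substituting one representative per
orbit of O positions under each molecule's automorphism group — the
result equals regenerating the S-formulae from scratch.
"""

from isospace import (
    Library,
    canonical_form,
    enumerate_isomers,
    parse_formula,
    substitute_heteroatom,
)

src = Library("C2H6O2")
for mol in enumerate_isomers(parse_formula("C2H6O2")):
    src.add(mol)
print(f"C2H6O2 isomers: {len(src)}")

subst = substitute_heteroatom(src, "O", "S", max_substitutions=1)
de_novo = {canonical_form(m) for m in enumerate_isomers(parse_formula("C2H6OS"))}
print(f"O->S substitution products: {len(subst)}")
print(f"de novo C2H6OS isomers:     {len(de_novo)}")
print("identical certificate sets:", set(subst.certificates()) == de_novo)
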