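"""Exhaustive α-amino-acid library plus a descriptor table.

Every member carries the H2N-CH(R)-COOH scaffold; the sweep covers all
graphical formulae up to the carbon cap.  Descriptors are the three
adaptive-analysis axes: hydrophobicity (logP), size (van der Waals
volume, Å³) and side-chain pKa (NaN = non-ionizable).
"""

from isospace import build_amino_acid_library, default_badlist, property_table

lib = build_amino_acid_library(3, bad=default_badlist("amino_acid"), o_range=(2, 3), n_range=(1, 1))
print(f"alpha-amino acids with <= 3 carbons (culled): {len(lib)} structures")

table = property_table(lib)
print(table[["smiles", "logp", "vdw_volume", "pka"]].to_string(index=False))
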