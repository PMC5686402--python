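"""Build a nucleoside-analogue library for a small formula space.

"B" is a univalent placeholder for the recognition moiety (e.g. a
nucleobase).  Members must pass the shipped stability badlist and
carry at least two free O-H/N-H groups so they could join a linear
polymer backbone.  The full riboside space C5H9O4B yields 227
structures with these rules (a few minutes); this example uses a
smaller space so it finishes in seconds.
"""

from isospace import NucleosideConstraints, build_nucleoside_library, default_badlist

lib = build_nucleoside_library(
    "C3H7O2B", NucleosideConstraints(2, default_badlist("nucleoside"))
)
print(f"C3H7O2B nucleoside analogues: {len(lib)} structures")
for cert in lib.certificates():
    print(" ", lib.molecules[cert])
print("(each line: one monomer candidate with >=2 polymerizable OH sites)")
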