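# Additive van der Waals volume scheme (A^3 per atom) following
# Zhao, Abraham & Zissimos, J. Org. Chem. 68 (2003) 7368-7373:
#   V_vdw = sum(atom contributions) - 5.92*N_bonds - 14.7*R_arom - 3.8*R_nonarom
# N_bonds counts bonds (not orders) including bonds to hydrogens.
# The univalent placeholder B contributes 0 (it stands for an
# unspecified attachment, constant within a fixed-formula library).
element,volume
H,7.24
C,20.58
N,15.60
O,14.71
S,24.43
B,0.0
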