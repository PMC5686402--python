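# Compact atomic-contribution logP parameterization (version 1).
# Additive per-atom scheme in the spirit of Wildman & Crippen,
# J. Chem. Inf. Comput. Sci. 39 (1999) 868-873: each atom is assigned
# an environment class and logP is the sum of class values (implicit
# hydrogens contribute through their heavy-atom classes H_on_C /
# H_on_hetero).  Values are a coarse re-parameterization chosen for
# internal consistency (alkane > alcohol ordering, hydrophilicity of
# N/O), not a copy of the published table; descriptor values are
# meaningful relative to this pinned table only.
class,value
C_sp3_hydrocarbon,0.144
C_sp3_hetero,-0.204
C_unsat_hydrocarbon,0.264
C_carbonyl,-0.205
C_unsat_hetero,-0.100
N_saturated,-1.019
N_unsaturated,-0.324
O_hydroxyl,-0.289
O_ether,-0.068
O_carbonyl,-0.120
S_any,0.255
B_placeholder,0.0
H_on_C,0.123
H_on_hetero,-0.268
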