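# Side-chain ionizable-group reference pKa values (water, 25 C).
# Rule-based class lookup: the side chain's highest-priority ionizable
# group determines the value; side chains with none are non-ionizable
# (absent).  Reference values are the textbook free-amino-acid
# side-chain constants (priority resolves multi-group side chains).
class,priority,pka
carboxyl,1,4.25
guanidino,2,12.48
imidazole,3,6.00
thiol,4,8.33
phenol,5,10.07
amine,6,10.53
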