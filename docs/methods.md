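# Methods

## Molecular model

Molecules are element-labelled connected multigraphs with bond orders
1–3 and fixed valences: C 4, N 3, O 2, S 2, H 1. Charges, radicals,
hypervalent states, isotopes and stereochemistry are outside the
model; a "molecule" here is a constitutional (connectivity) isomer
class. Hydrogens are implicit — each atom carries
`valence − Σ incident bond orders` of them — so enumeration works on
heavy-atom graphs only.

Aromatic rings are represented as explicit Kekulé assignments, and
identity is Kekulé-level: two assignments count as the same isomer
exactly when they are graph-isomorphic. For benzene itself (and other
symmetric rings) the alternating-bond rotation is an automorphism, so
the assignments collapse to one isomer; for some substitution
patterns (e.g. ortho-disubstituted benzenes) the two assignments are
graph-distinct and are counted separately. This convention is exact
for the spaces studied here — the riboside space has one degree of
unsaturation and the small amino-acid sweeps cannot form aromatic
rings — and the C6H6 benchmark count (217) is reproduced under it.

`B` is spelled like boron but is a **univalent placeholder**: it forms
exactly one single bond and stands for an unspecified recognition
moiety (a nucleobase, in the nucleoside work). Boron chemistry itself
is unsupported.

## Certificates and symmetry

Isomorphism classes are identified by a canonical form: an equitable
partition refinement (atoms split by element, then iteratively by the
multiset of (bond order, neighbor cell) pairs) followed by a
backtracking search for the lexicographically maximal adjacency
serialization over the refined cells. All labelings attaining the
maximum are collected, which yields the automorphism group as a
by-product. The serialization (element sequence + lower-triangular
bond rows) is the certificate used for deduplication everywhere.
Tests cross-check both the certificate and the automorphism groups
against independent oracles (igraph VF2 with vertex/edge colors, and
exhaustive permutation search at small sizes).

## Enumeration

Given an exact formula, the generator fills the upper triangle of a
bond-order matrix row by row over a fixed atom order (elements sorted
by decreasing valence). Sound prunes: residual-valence bounds; a total
bond-order budget fixed by the hydrogen count; connectivity look-ahead
(a closed component that cannot reach later atoms is abandoned); and
an adjacent-transposition semicanonicity test, a necessary condition
for the matrix to be the lexicographically maximal representative of
its class. Remaining duplicates are removed at emission by
certificate; output order is lexicographic by certificate, so runs are
byte-reproducible. Structural constraints (badlist, goodlist, ring
size) are checked at emission, which makes
generate-with-badlist ≡ generate-then-filter exact by construction.

A deliberately naive exhaustive enumerator (`brute_force_enumerate`,
all bond assignments over all atom pairs, valence bookkeeping only) is
kept as an in-package oracle; the test suite verifies certificate-set
equality against it for **every** graphical CHNOSB formula with ≤5
heavy atoms (~650 formulae, ~11 000 structures).

Fuzzy formulae expand to the Cartesian product of their element
ranges, filtered by a graphical-realizability predicate (even valence
sum, integer non-negative unsaturation, spanning-bond budget, bond
order ≤3 for two-atom formulae). When hydrogen is omitted, every
hydrogen count consistent with these conditions is included — the safe
general mode, since published formula-space notations for the hydrogen
index are not always interpretable. The default expansion cap is
10 000 formulae; exceeding it is an error advising narrower ranges.

## Substructure patterns

The pattern dialect is a SMARTS subset: element symbols, `*` wildcard,
bond symbols `- = # ~` (any), branches, ring closures, and bracket
atoms `[OH]`/`[NH2]` demanding a minimum implicit-hydrogen count.
Matching is injective subgraph embedding by backtracking. The badlist
file format is one pattern per line with `#` comments carrying the
chemical rationale; a molecule removed by several patterns is
attributed to the earliest (first-match attribution), so per-pattern
removal counts sum to the total removed.

## Nucleoside-analogue libraries and the 227-structure space

A nucleoside analogue is defined operationally: exactly one
placeholder `B` (the recognition moiety) and at least two *free
functional groups* — O-H or N-H sites on heavy atoms not bonded to the
placeholder — so the monomer can be coupled into a linear polymer
backbone. For the natural-riboside formula C5H9O4B (one degree of
unsaturation: each isomer is either monocyclic and saturated or
acyclic with one double bond) the raw space holds 32 710
constitutional isomers.

The shipped stability badlist (`data/nucleoside_stability.badlist`)
encodes survival under aqueous, moderate-pH conditions: no peroxides
(O-O), no O- or acyl-attachment of the placeholder (O-B, B-C=O), no
hemiacetal/geminal-diol or orthoester carbons, no enols or enol
ethers, no free aldehydes or ketones (reactive electrophiles), and no
3- or 4-membered rings (ring strain). Acetals (the glycoside-like
motif), carboxylic acids and esters are retained. With the ≥2
functional-group rule this leaves **227** structures, the natural
β-ribofuranoside constitution among them.

The published forbidden-substructure list for this compound class is
not reproduced in the sources available here, so this badlist is a
reconstruction: candidate instability motifs were enumerated, the
sensitivity of the library size to each pattern was tabulated over the
raw 32 710-isomer space, and the minimal chemically coherent
configuration reproducing the published library size (with the natural
riboside surviving) was selected and documented pattern by pattern.
`FilterReport` makes the per-pattern sensitivity auditable on every
run; removing count-neutral patterns (e.g. the orthoester rule, whose
matches are already excluded by other rules) does not change the
total. The count should be read with that provenance in mind: the
*pipeline* (complete enumeration → documented badlist → functional-
group rule) is the method; the badlist is one documented, defensible
instantiation of "likely stability under biochemically relevant
conditions".

## α-amino-acid libraries

Members must contain the α-amino-acid scaffold H2N-CH(R)-COOH,
expressed as the goodlist pattern `[NH][CH]C(=O)[OH]` (N-substituted,
proline-like members require an explicit flag relaxing the N-H
requirement; default off). The "unique" (UL) mode sweeps all graphical
formulae with 2..max carbons, N and O (optionally S) in configurable
ranges and free hydrogen; the "combined" (CL) mode unions the 20 coded
amino acids with a small-member exhaustive sweep, recording the
construction in provenance. The shipped amino-acid badlist is again a
reconstruction in spirit (peroxides, azo/azide chains, hemiacetals,
enols/enamines, aminals, strained rings, …, each with rationale). The
test suite exercises the CI-scale surrogate — libraries at ≤3 carbons
with narrowed element ranges (N 1, O 2–3) — asserting monotone growth
in the carbon cap, 100 % scaffold matching and duplicate-freeness;
the full ≤6-carbon published-scale run uses the same code path with
wider ranges and more time.

## Heteroatom substitution

Divalent O can be replaced by divalent S without regenerating: for
each molecule, subsets of O positions (up to a configured size) are
enumerated one representative per orbit under the automorphism group,
since symmetry-equivalent sites give identical products. The library-
level result is deduplicated by certificate and is tested to equal
de novo enumeration of the substituted formulae (single and double
substitution).

## Descriptors

* **logP** — sum of per-atom environment-class contributions from a
  pinned table (`data/logp_contributions.csv`), a compact
  re-parameterization in the additive spirit of Wildman & Crippen
  (1999). Values are internally consistent (alkane > alcohol, N/O
  hydrophilic) but are not numerically comparable to any published
  axis; only relative placement matters for the adaptive analysis.
* **V_vdw** (Å³) — the additive scheme of Zhao, Abraham & Zissimos
  (2003): Σ atomic volumes − 5.92·N_bonds − 3.8 per ring (aromaticity
  is not perceived, so all rings take the non-aromatic correction; a
  constant offset that cancels in within-library comparisons). Within
  a fixed formula this makes volume a function of bond and ring counts
  only — for C5H9O4B the cyclic isomers are uniformly the most compact
  — so the "natural riboside is among the most compact isomers" claim
  is tested as a rank statement: the fraction of library members with
  strictly smaller volume is below one decile.
* **pKa** — rule-based class lookup for the α-amino-acid side chain
  (carboxyl 4.25, guanidino 12.48, imidazole 6.00, thiol 8.33, phenol
  10.07, amine 10.53), `None` when no ionizable group is present.
  Amide and aryl/enamine nitrogens are excluded from the amine class.
  Classification is Kekulé-pattern based; exotic tautomer spellings of
  a ring may evade it. Members with absent pKa are excluded from the
  pKa axis statistics (resolved counts are reported).
* **Wiener index** — sum of heavy-atom shortest-path lengths.

Heats of formation are not computed; an external-column import hook on
the property table (`property_table(..., extra=...)`) lets
quantum-chemistry results join by certificate.

## Adaptive-alphabet analysis

Coverage of an axis by a set is summarized by range (max − min) and
evenness `1 − CV(gaps)/√(k−1)` over the k gaps between consecutive
sorted values — 1 for perfectly equidistant values, 0 when all spread
sits in a single gap, affine-invariant, clipped to [0, 1]. The
literature names "range and evenness" without a formula; this gap-CV
definition is the package's choice and the statistic functions are
plain and replaceable for sensitivity analysis. Dominance ("better
than the reference") is strict Pareto: ≥ on all six axis statistics,
> on at least one. `sample_random_sets` draws uniformly without
replacement, counts dominating sets, and is exactly reproducible given
a seed.

The synthetic validation library plants a three-valued axis (two
ordinary levels plus an extreme level in 10 % of members) and constant
remaining axes, so a draw dominates iff it mixes extreme and ordinary
members — a probability with a closed hypergeometric form. The
Monte-Carlo fraction must land within three standard errors of it.
What this validates is the dominance counting and sampling machinery,
not any claim about real amino-acid space: the synthetic table has no
property correlations, no clustered values and no unresolved entries
beyond the constant axes.

## Numerical and scale choices

All randomness flows from explicit integer seeds (numpy Generator).
Descriptor values are rounded to 1e-6 to keep CSV round-trips exact.
The test suite runs the full oracle sweep at ≤5 heavy atoms, the
complete C5H9O4B pipeline (one shared ~3-minute enumeration per
session), and CI-scale library surrogates; the published-scale
≤6-carbon amino-acid sweep is the same code with wider parameters and
is left to explicit runs. The fuzzy-expansion cap (10 000) and the
brute-force oracle cap (7 heavy atoms) guard against accidental
combinatorial explosions.

## Known limitations

* No charges, radicals, tautomer merging or stereochemistry; stereo
  counts reported in the literature (factors ~2–10) are out of scope.
* The SMILES dialect is a Kekulé-only subset; lowercase aromatic
  input is rejected rather than kekulized.
* Badlists are documented reconstructions, not the historical lists;
  counts that depend on them carry that caveat explicitly.
* logP/pKa parameterizations are coarse class schemes fit for ranking
  within a library, not for predicting measured values.
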