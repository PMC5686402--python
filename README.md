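# isospace

Exhaustive constitutional-isomer enumeration and virtual-library
analysis for origins-of-life chemical spaces.

## The problem

Biochemistry uses a tiny corner of organic chemical space: 20 coded
amino acids, four ribonucleosides. Were these selected for cause, or
inherited by accident? Answering that requires knowing the
*alternatives* — every molecule that could have played the same role —
and chemical databases cannot provide them, because they catalogue
what was synthesized, not what is possible. `isospace` generates the
alternatives from first principles: given a molecular formula, it
enumerates **every** connected molecule satisfying fixed valences
(Lewis electron pairing), exactly once, then culls the chemically
implausible with forbidden-substructure lists and analyzes what
remains. It is written for computational chemists and origins-of-life
researchers who need complete, reproducible compound libraries rather
than database snapshots.

## What it does

* **Structure generation** — complete, non-redundant enumeration of
  the constitutional isomers of an exact or *fuzzy* formula
  (`C2-6H0-13N1O2-4`), by a canonically pruned search over bond-order
  matrices with certificate deduplication. Valences are fixed (C4, N3,
  O2, S2, H1); `B` is a univalent placeholder for an arbitrary
  attachment such as a nucleobase.
* **Badlist/goodlist filtering** — SMARTS-subset substructure patterns
  suppress unstable motifs (peroxides, enols, hemiacetals, …) or
  require a scaffold; removals are accounted per pattern.
* **Domain libraries** — α-amino acids (every member carries
  H2N-CH(R)-COOH) and nucleoside analogues (one placeholder, a
  stability badlist, ≥2 free O-H/N-H groups for polymerization).
* **Symmetry-aware substitution** — O→S replacement one orbit at a
  time under each molecule's automorphism group, equivalent to de novo
  generation of the sulfur formulae.
* **Descriptors** — additive logP, van der Waals volume
  (Zhao–Abraham–Zissimos scheme), rule-based side-chain pKa, Wiener
  index.
* **Adaptive-alphabet analysis** — compares a reference alphabet (the
  coded 20) against random same-size sets on *range* and *evenness* of
  each property axis; a set is "better" when it is at least as good on
  every axis statistic and strictly better somewhere.

## Worked example

```sh
$ python examples/01_enumerate_isomers.py
C2H6O: 2 constitutional isomers
C2H4O: 3 constitutional isomers
C4H10: 2 constitutional isomers
C6H6: 217 constitutional isomers

The three C2H4O isomers (oxirane, acetaldehyde, vinyl alcohol):
  CC=O
  C(CO1)1
  C(=C)O
```

C2H6O has exactly two isomers (ethanol and dimethyl ether); C6H6 has
217 — the classic benchmark for exhaustive generators. The other
examples build a nucleoside-analogue library (`02`), an α-amino-acid
library with its logP/volume/pKa table (`03`), check that symmetry
substitution equals de novo generation (`04`), and validate the
adaptive Monte-Carlo against a closed-form expectation (`05`).

The same operations are available from a thin CLI:

```sh
isospace generate --formula C5H9O4B --count-only
isospace library nucleosides --space C5H9O4B --out ribosides.smi
isospace descriptors --in ribosides.smi --out props.csv
```

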