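"""Domain library builders: α-amino acids, nucleoside analogues, and
symmetry-aware heteroatom substitution.

A :class:`Library` is a certificate-keyed, deduplicated set of
molecules with provenance (formula space, constraints, builder
parameters).  Two builders implement the studied compound classes:

* α-amino acids — every member carries the H2N-CH(R)-COOH scaffold
  (side chain R on the α-carbon); the "unique" (UL) mode sweeps the
  whole formula space up to a carbon cap, while the "combined" (CL)
  mode anchors on the 20 genetically coded amino acids plus an
  exhaustive small-member sweep.
* nucleoside analogues — one univalent placeholder ``B`` (the
  recognition moiety, e.g. a nucleobase), a stability badlist, and at
  least two free polymerizable groups (O-H/N-H sites away from the
  placeholder attachment) so the monomer can join a linear backbone.

Because O and S share a valence, S-containing libraries can be derived
from O-containing ones by orbit-unique substitution instead of de novo
generation; the orbits of O-position subsets under the automorphism
group make the product set duplicate-free.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

from .chemgraph import (
    PLACEHOLDER,
    MolecularGraph,
    automorphism_group,
    canonical_form,
    from_smiles,
    to_smiles,
    valence,
)
from .formula import Formula, FuzzyFormula, expand_fuzzy, parse_formula
from .generator import GenerationConstraints, enumerate_isomers
from .patterns import Badlist, SubstructurePattern, load_badlist, match, parse_pattern

__all__ = [
    "Library",
    "NucleosideConstraints",
    "ALPHA_AMINO_ACID_PATTERN",
    "NATURAL_RIBOSIDE_SMILES",
    "build_amino_acid_library",
    "build_nucleoside_library",
    "substitute_heteroatom",
    "library_diff",
    "free_functional_groups",
    "coded_amino_acids",
    "default_badlist",
]

#: α-amino-acid scaffold: N with >=1 H, bonded to a C with >=1 H,
#: bonded to a carboxyl group.
ALPHA_AMINO_ACID_PATTERN = "[NH][CH]C(=O)[OH]"

#: Constitution of the natural β-ribofuranoside (stereochemistry
#: ignored): placeholder on C1', furanose ring O, 2'/3'-OH, 5'-CH2OH.
NATURAL_RIBOSIDE_SMILES = "BC1OC(CO)C(O)C1O"


@dataclass
class Library:
    """Deduplicated, certificate-keyed molecule set with provenance."""

    name: str
    molecules: Dict[str, str] = field(default_factory=dict)  # cert -> smiles
    flags: Dict[str, Dict] = field(default_factory=dict)  # cert -> metadata
    provenance: Dict = field(default_factory=dict)

    def add(self, mol: MolecularGraph, **meta) -> str:
        cert = canonical_form(mol)
        if cert not in self.molecules:
            self.molecules[cert] = to_smiles(mol)
        if meta:
            self.flags.setdefault(cert, {}).update(meta)
        return cert

    def __len__(self) -> int:
        return len(self.molecules)

    def __contains__(self, cert: str) -> bool:
        return cert in self.molecules

    def certificates(self) -> List[str]:
        return sorted(self.molecules)

    def iter_molecules(self) -> Iterator[MolecularGraph]:
        for cert in self.certificates():
            yield from_smiles(self.molecules[cert])

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """SMILES one per line (certificate-sorted) + JSON sidecar."""
        path = str(path)
        with open(path, "w") as fh:
            for cert in self.certificates():
                fh.write(self.molecules[cert] + "\n")
        sidecar = {
            "name": self.name,
            "size": len(self),
            "provenance": self.provenance,
            "flags": self.flags,
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path, name: str | None = None) -> "Library":
        lib = cls(name or str(path))
        with open(path) as fh:
            for line in fh:
                line = line.split()[0] if line.split() else ""
                if line:
                    lib.add(from_smiles(line))
        try:
            with open(str(path) + ".json") as fh:
                sidecar = json.load(fh)
            lib.provenance = sidecar.get("provenance", {})
            lib.flags = sidecar.get("flags", {})
            lib.name = sidecar.get("name", lib.name)
        except FileNotFoundError:
            pass
        return lib


def coded_amino_acids() -> Library:
    """The 20 amino acids of the standard genetic code (Kekulé SMILES)."""
    lib = Library("coded20", provenance={"source": "standard genetic code"})
    text = resources.files("isospace.data").joinpath("coded_amino_acids.smi").read_text()
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        lib.add(from_smiles(parts[0]), name=parts[1] if len(parts) > 1 else "")
    return lib


def default_badlist(which: str) -> Badlist:
    """Shipped plausibility badlists (``amino_acid`` or ``nucleoside``).

    These are reconstructions in the spirit of published forbidden-
    substructure lists (each entry carries its rationale in the file);
    they are not copies of any published list.
    """
    fname = {"amino_acid": "amino_acid.badlist", "nucleoside": "nucleoside_stability.badlist"}[
        which
    ]
    with resources.as_file(resources.files("isospace.data").joinpath(fname)) as p:
        return load_badlist(p, name=which)


# ---------------------------------------------------------------------------
# α-amino acids
# ---------------------------------------------------------------------------


def build_amino_acid_library(
    max_carbons: int,
    elements: Sequence[str] = ("C", "H", "N", "O"),
    bad: Optional[Badlist] = None,
    mode: str = "UL",
    n_range: Tuple[int, int] = (1, 2),
    o_range: Tuple[int, int] = (2, 4),
    s_range: Tuple[int, int] = (0, 1),
    allow_n_substituted: bool = False,
    cl_sweep_carbons: int = 3,
) -> Library:
    """Exhaustive (UL) or coded-anchored (CL) α-amino-acid library.

    UL sweeps every graphical formula with 2..max_carbons carbons,
    nitrogen/oxygen/(optional sulfur) in the given ranges and free
    hydrogen, keeping molecules that contain the α-amino-acid scaffold
    and pass the badlist.  CL unions the coded twenty (up to the carbon
    cap) with a UL sweep capped at *cl_sweep_carbons*.

    ``allow_n_substituted`` relaxes the N-H requirement of the
    scaffold so proline-like (N-alkylated) members qualify.
    """
    if max_carbons < 2:
        raise ValueError("max_carbons must be >= 2 (glycine has two carbons)")
    if mode not in ("UL", "CL"):
        raise ValueError(f"unknown mode {mode!r}")
    scaffold_text = (
        ALPHA_AMINO_ACID_PATTERN.replace("[NH]", "N")
        if allow_n_substituted
        else ALPHA_AMINO_ACID_PATTERN
    )
    scaffold = parse_pattern(scaffold_text)
    lib = Library(f"{mode}-C{max_carbons}")
    lib.provenance = {
        "builder": "build_amino_acid_library",
        "mode": mode,
        "max_carbons": max_carbons,
        "elements": list(elements),
        "n_range": list(n_range),
        "o_range": list(o_range),
        "s_range": list(s_range) if "S" in elements else [0, 0],
        "badlist": bad.name if bad else None,
        "scaffold": scaffold_text,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    sweep_carbons = max_carbons if mode == "UL" else min(max_carbons, cl_sweep_carbons)
    constraints = GenerationConstraints(badlist=bad, goodlist=[scaffold])
    for n_c in range(2, sweep_carbons + 1):
        ranges: Dict[str, Tuple[int, int]] = {"C": (n_c, n_c), "N": n_range, "O": o_range}
        if "S" in elements:
            ranges["S"] = s_range
        for f in expand_fuzzy(FuzzyFormula(ranges)):
            for mol in enumerate_isomers(f, constraints):
                lib.add(mol, formula=str(f))
    if mode == "CL":
        for mol in coded_amino_acids().iter_molecules():
            if sum(1 for el in mol.atoms if el == "C") <= max_carbons:
                if match(scaffold, mol) and (bad is None or not any(
                    match(p, mol) for p in bad.patterns()
                )):
                    lib.add(mol, coded=True)
    return lib


# ---------------------------------------------------------------------------
# Nucleoside analogues
# ---------------------------------------------------------------------------


@dataclass
class NucleosideConstraints:
    """Selection rules for nucleoside-analogue libraries."""

    min_free_functional_groups: int = 2
    badlist: Optional[Badlist] = None

    def __post_init__(self):
        if self.min_free_functional_groups < 0:
            raise ValueError("min_free_functional_groups must be >= 0")


def free_functional_groups(mol: MolecularGraph) -> int:
    """Free polymerizable sites: O-H and N-H groups on heavy atoms not
    bonded to the placeholder (the placeholder attachment is already
    spoken for)."""
    count = 0
    for i, el in enumerate(mol.atoms):
        if el not in ("O", "N"):
            continue
        if mol.implicit_hydrogens(i) < 1:
            continue
        if any(mol.atoms[j] == PLACEHOLDER for j, _ in mol.neighbors(i)):
            continue
        count += 1
    return count


def build_nucleoside_library(
    space: FuzzyFormula | Formula | str,
    constraints: Optional[NucleosideConstraints] = None,
) -> Library:
    """Nucleoside-analogue library over a (fuzzy) formula space.

    Every expanded formula must contain exactly one placeholder ``B``.
    Members pass the stability badlist and carry at least
    ``min_free_functional_groups`` free O-H/N-H sites.  The natural
    riboside constitution is flagged when its formula is in the space.
    """
    if isinstance(space, str):
        space = parse_formula(space)
    if isinstance(space, Formula):
        formulae = [space]
        space_str = str(space)
    else:
        if space.as_dict().get(PLACEHOLDER, (0, 0)) != (1, 1):
            raise ValueError("placeholder B count must be fixed at exactly 1")
        formulae = expand_fuzzy(space)
        space_str = str(space)
    constraints = constraints or NucleosideConstraints()
    natural_cert = canonical_form(from_smiles(NATURAL_RIBOSIDE_SMILES))
    lib = Library(f"nucleosides-{space_str}")
    lib.provenance = {
        "builder": "build_nucleoside_library",
        "space": space_str,
        "min_free_functional_groups": constraints.min_free_functional_groups,
        "badlist": constraints.badlist.name if constraints.badlist else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    gen_constraints = GenerationConstraints(badlist=constraints.badlist)
    for f in formulae:
        if f[PLACEHOLDER] != 1:
            raise ValueError(f"formula {f} must contain exactly one placeholder B")
        for mol in enumerate_isomers(f, gen_constraints):
            if free_functional_groups(mol) < constraints.min_free_functional_groups:
                continue
            cert = lib.add(mol, formula=str(f))
            if cert == natural_cert:
                lib.flags.setdefault(cert, {})["natural_riboside"] = True
    return lib


# ---------------------------------------------------------------------------
# Symmetry-aware heteroatom substitution and diffs
# ---------------------------------------------------------------------------


def substitute_heteroatom(
    lib: Library | Iterable[MolecularGraph],
    frm: str = "O",
    to: str = "S",
    max_substitutions: int = 1,
) -> Library:
    """Replace *frm* atoms by *to* without regenerating de novo.

    For each molecule, subsets of *frm* positions (size 1..max) are
    taken one per orbit under the automorphism group — symmetry-
    equivalent substitution sites give identical products, so only one
    representative per orbit is emitted.  The result is deduplicated
    across the whole library and equals de-novo generation on the
    substituted formulae under the same constraints.
    """
    if valence(frm) != valence(to):
        raise ValueError(
            f"substitution requires equal valences: {frm}={valence(frm)}, "
            f"{to}={valence(to)}"
        )
    mols = lib.iter_molecules() if isinstance(lib, Library) else lib
    out = Library(
        f"substituted-{frm}to{to}",
        provenance={
            "builder": "substitute_heteroatom",
            "from": frm,
            "to": to,
            "max_substitutions": max_substitutions,
            "source": lib.name if isinstance(lib, Library) else "<stream>",
        },
    )
    for mol in mols:
        positions = [i for i, el in enumerate(mol.atoms) if el == frm]
        if not positions:
            continue
        group = automorphism_group(mol)
        for size in range(1, min(max_substitutions, len(positions)) + 1):
            seen_orbits: Set[Tuple[int, ...]] = set()
            for subset in itertools.combinations(positions, size):
                orbit_rep = min(
                    tuple(sorted(sigma[i] for i in subset)) for sigma in group
                )
                if orbit_rep in seen_orbits:
                    continue
                seen_orbits.add(orbit_rep)
                atoms = list(mol.atoms)
                for i in subset:
                    atoms[i] = to
                out.add(MolecularGraph(tuple(atoms), dict(mol.bonds)))
    return out


def library_diff(a: Library, b: Library) -> Tuple[Set[str], Set[str], Set[str]]:
    """Partition certificates into (only in a, only in b, shared)."""
    ca, cb = set(a.molecules), set(b.molecules)
    return ca - cb, cb - ca, ca & cb
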