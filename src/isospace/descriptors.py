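"""Additive physico-chemical descriptors and topological indices.

Three property axes drive the adaptive-alphabet analysis:

* ``logp`` — hydrophobicity as a sum of per-atom environment-class
  contributions (pinned table in ``data/logp_contributions.csv``);
* ``vdw_volume`` — van der Waals volume in Å³ by the additive
  bond/ring-corrected scheme of Zhao, Abraham & Zissimos (2003)
  (``data/vdw_contributions.csv``);
* ``pka_estimate`` — rule-based side-chain acid-dissociation class
  lookup for α-amino acids; ``None`` when the side chain carries no
  ionizable group.

All descriptors are deterministic, permutation-invariant functions of
the molecular graph; none require 3-D geometry.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional

import networkx as nx
import pandas as pd

from .chemgraph import PLACEHOLDER, MolecularGraph, canonical_form, to_smiles
from .patterns import embeddings, match, parse_pattern

__all__ = [
    "logp",
    "vdw_volume",
    "pka_estimate",
    "wiener_index",
    "property_table",
    "classify_atom",
]


def _load_table(name: str) -> Dict[str, float]:
    text = resources.files("isospace.data").joinpath(name).read_text()
    out: Dict[str, float] = {}
    for row in csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#"))
    ):
        key = row.get("class") or row.get("element")
        out[key] = float(row.get("value") or row.get("volume"))
    return out


@lru_cache(maxsize=1)
def _logp_table() -> Dict[str, float]:
    return _load_table("logp_contributions.csv")


@lru_cache(maxsize=1)
def _vdw_table() -> Dict[str, float]:
    return _load_table("vdw_contributions.csv")


@lru_cache(maxsize=1)
def _pka_table() -> Dict[str, float]:
    text = resources.files("isospace.data").joinpath("pka_classes.csv").read_text()
    out = {}
    for row in csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#"))
    ):
        out[row["class"]] = float(row["pka"])
    return out


def classify_atom(mol: MolecularGraph, i: int) -> str:
    """Environment class of heavy atom *i* for the logP table."""
    el = mol.atoms[i]
    nbrs = mol.neighbors(i)
    has_multiple = any(order > 1 for _, order in nbrs)
    hetero = any(mol.atoms[j] in ("N", "O", "S") for j, _ in nbrs)
    if el == "C":
        if any(mol.atoms[j] == "O" and order == 2 for j, order in nbrs):
            return "C_carbonyl"
        if has_multiple:
            return "C_unsat_hetero" if hetero else "C_unsat_hydrocarbon"
        return "C_sp3_hetero" if hetero else "C_sp3_hydrocarbon"
    if el == "N":
        return "N_unsaturated" if has_multiple else "N_saturated"
    if el == "O":
        if has_multiple:
            return "O_carbonyl"
        return "O_hydroxyl" if mol.implicit_hydrogens(i) >= 1 else "O_ether"
    if el == "S":
        return "S_any"
    if el == PLACEHOLDER:
        return "B_placeholder"
    if el == "H":
        return "H_on_C"
    raise ValueError(f"atom {i}: element {el!r} outside the parameter table")


def logp(mol: MolecularGraph) -> float:
    """Additive atomic-contribution hydrophobicity (pinned table v1)."""
    mol.validate()
    table = _logp_table()
    total = 0.0
    for i, el in enumerate(mol.atoms):
        if el == "H":
            total += table["H_on_C"]
            continue
        total += table[classify_atom(mol, i)]
        h = mol.implicit_hydrogens(i)
        total += h * (table["H_on_C"] if el == "C" else table["H_on_hetero"])
    return round(total, 6)


def vdw_volume(mol: MolecularGraph) -> float:
    """Van der Waals volume (Å³), Zhao-Abraham-Zissimos additive scheme.

    ``V = Σ atom contributions − 5.92·N_bonds − 14.7·R_arom − 3.8·R_non``
    with ``N_bonds`` the bond count (orders ignored) including implicit
    hydrogens.  Aromaticity is not perceived here, so all rings take
    the non-aromatic correction.
    """
    mol.validate()
    table = _vdw_table()
    total = 0.0
    n_h = 0
    for i, el in enumerate(mol.atoms):
        if el not in table:
            raise ValueError(f"atom {i}: element {el!r} outside the parameter table")
        total += table[el]
        if el != "H":
            n_h += mol.implicit_hydrogens(i)
    total += n_h * table["H"]
    # Bond count ignores orders; implicit hydrogens add one bond each.
    n_bonds = len(mol.bonds) + n_h
    rings = len(mol.bonds) - mol.n_atoms + 1  # cyclomatic number
    return round(total - 5.92 * n_bonds - 3.8 * max(rings, 0), 6)


# -- pKa ---------------------------------------------------------------------

_ALPHA_SCAFFOLD = "[NH][CH]C(=O)[OH]"

_SIDE_CHAIN_CLASSES = [
    # (class name, pattern); checked in table priority order
    ("carboxyl", "OC(=O)*"),
    ("guanidino", "NC(=N)N"),
    ("imidazole", "C1=CNC=N1"),
    ("thiol", "[SH]"),
    ("phenol", "[OH]C1=CC=CC=C1"),
    ("amine", "[NH]"),
]


def pka_estimate(mol: MolecularGraph) -> Optional[float]:
    """Side-chain pKa by ionizable-group class (α-amino-acid context).

    Locates the α-amino-acid scaffold, then classifies the remaining
    (side-chain) atoms by the highest-priority ionizable group.
    Returns ``None`` for non-ionizable side chains or when no scaffold
    is present.
    """
    mol.validate()
    scaffold = parse_pattern(_ALPHA_SCAFFOLD)
    embs = embeddings(scaffold, mol)
    if not embs:
        return None
    table = _pka_table()
    best: Optional[float] = None
    best_priority = 99
    priorities = {name: k for k, (name, _) in enumerate(_SIDE_CHAIN_CLASSES)}
    for emb in embs:
        backbone = set(emb.values())
        for name, pat_text in _SIDE_CHAIN_CLASSES:
            if priorities[name] >= best_priority:
                continue
            pat = parse_pattern(pat_text)
            for m in embeddings(pat, mol):
                if set(m.values()) & backbone:
                    continue
                if name == "amine" and not _is_basic_amine(mol, m[0]):
                    continue
                best = table[name]
                best_priority = priorities[name]
                break
    return best


def _is_basic_amine(mol: MolecularGraph, n_idx: int) -> bool:
    """Saturated N-H on sp3 carbons only: excludes amide nitrogens and
    aniline/pyrrole-type N whose lone pair is delocalized."""
    nbrs = mol.neighbors(n_idx)
    if any(order > 1 for _, order in nbrs):
        return False
    for j, _ in nbrs:
        if mol.atoms[j] == "C" and any(o > 1 for _, o in mol.neighbors(j)):
            return False  # amide / enamine / aryl amine
    return True


def wiener_index(mol: MolecularGraph) -> int:
    """Sum of shortest-path lengths over unordered heavy-atom pairs."""
    g = nx.Graph()
    heavy = [i for i, el in enumerate(mol.atoms) if el != "H"]
    g.add_nodes_from(heavy)
    for (i, j) in mol.bonds:
        if mol.atoms[i] != "H" and mol.atoms[j] != "H":
            g.add_edge(i, j)
    total = 0
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for a in heavy:
        for b in heavy:
            if a < b:
                total += lengths[a][b]
    return total


def property_table(
    mols,
    extra: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One descriptor row per molecule, keyed and sorted by certificate.

    *mols* is an iterable of molecules or a library exposing
    ``iter_molecules()``.  Descriptor failures are recorded in an
    ``error`` column rather than raised.  *extra* (indexed by
    certificate) is left-joined to support externally computed columns
    such as heats of formation.
    """
    if hasattr(mols, "iter_molecules"):
        mols = mols.iter_molecules()
    rows: List[Dict] = []
    for mol in mols:
        cert = canonical_form(mol)
        row: Dict = {"certificate": cert, "smiles": to_smiles(mol)}
        try:
            row["logp"] = logp(mol)
            row["vdw_volume"] = vdw_volume(mol)
            row["pka"] = pka_estimate(mol)
            row["wiener"] = wiener_index(mol)
            row["error"] = ""
        except Exception as exc:  # recorded per-row, not fatal
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows).drop_duplicates("certificate")
    df = df.sort_values("certificate").reset_index(drop=True)
    if extra is not None:
        df = df.merge(extra, how="left", left_on="certificate", right_index=True)
    return df
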