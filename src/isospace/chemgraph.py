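"""Molecular graphs with fixed valences, canonical forms and symmetry.

The unit of enumeration throughout the package is the *constitutional
isomer*: a connected multigraph whose nodes are atoms (element-labelled)
and whose edges are covalent bonds of order 1-3.  Hydrogens are implicit
by default — every atom carries ``valence(element) - bond_order_sum``
hydrogens — which keeps the graphs small and makes a molecular formula a
pure statement about heavy-atom connectivity.

The model is deliberately austere: fixed integer valences, no charges,
no radicals, no aromatic bond type (aromatic rings live as explicit
Kekulé assignments), no stereochemistry.  The univalent placeholder
element, spelled ``B`` in formulae and SMILES, stands for an arbitrary
monovalent attachment point (e.g. a nucleobase in nucleoside-analogue
enumeration) and is unrelated to boron.

Canonical forms are computed by iterative partition refinement followed
by a backtracking search for the lexicographically maximal adjacency
serialization over label-preserving relabelings; the search doubles as
an automorphism-group computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "VALENCES",
    "PLACEHOLDER",
    "ValenceError",
    "MolecularGraph",
    "canonical_form",
    "canonical_order",
    "are_isomorphic",
    "automorphism_group",
    "add_implicit_hydrogens",
    "to_smiles",
    "from_smiles",
    "to_molblock",
]

#: Fixed valence model: bond-order sums each atom must satisfy once
#: implicit hydrogens are counted.  ``B`` is the univalent placeholder.
VALENCES: Dict[str, int] = {"C": 4, "N": 3, "O": 2, "S": 2, "H": 1, "B": 1}

PLACEHOLDER = "B"


class ValenceError(ValueError):
    """An atom exceeds its fixed valence (carries the offending index)."""

    def __init__(self, message: str, atom_index: int | None = None):
        super().__init__(message)
        self.atom_index = atom_index


def valence(element: str) -> int:
    try:
        return VALENCES[element]
    except KeyError:
        raise ValueError(f"element {element!r} has no assigned valence") from None


@dataclass(frozen=True)
class MolecularGraph:
    """Element-labelled connected multigraph with bond orders 1-3.

    ``atoms`` is an ordered tuple of element symbols; ``bonds`` maps
    index pairs ``(i, j)`` with ``i < j`` to a bond order.  At most one
    bond record exists per pair — multiplicity is carried by the order.
    """

    atoms: Tuple[str, ...]
    bonds: Dict[Tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        norm = {}
        for (i, j), order in dict(self.bonds).items():
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not 1 <= order <= 3:
                raise ValueError(f"bond order {order} outside 1..3")
            key = (i, j) if i < j else (j, i)
            if key in norm:
                raise ValueError(f"duplicate bond record for {key}")
            norm[key] = order
        object.__setattr__(self, "bonds", norm)

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> List[Tuple[int, int]]:
        """(neighbor index, bond order) pairs of atom *i*."""
        out = []
        for (a, b), order in self.bonds.items():
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def bond_order_sum(self, i: int) -> int:
        return sum(order for _, order in self.neighbors(i))

    def implicit_hydrogens(self, i: int) -> int:
        return valence(self.atoms[i]) - self.bond_order_sum(i)

    def heavy_degree(self, i: int) -> int:
        return sum(1 for _ in self.neighbors(i))

    def adjacency_matrix(self) -> List[List[int]]:
        n = self.n_atoms
        adj = [[0] * n for _ in range(n)]
        for (i, j), order in self.bonds.items():
            adj[i][j] = order
            adj[j][i] = order
        return adj

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise if valences are exceeded or the graph is disconnected."""
        for i, el in enumerate(self.atoms):
            v = valence(el)
            s = self.bond_order_sum(i)
            if s > v:
                raise ValenceError(
                    f"atom {i} ({el}) has bond-order sum {s} > valence {v}", i
                )
        if self.n_atoms > 1 and not self.is_connected():
            raise ValueError("molecular graph must be connected")

    def is_connected(self) -> bool:
        n = self.n_atoms
        if n <= 1:
            return True
        adj = [[] for _ in range(n)]
        for (i, j) in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    def formula(self) -> Dict[str, int]:
        """Element counts including implicit hydrogens."""
        counts: Dict[str, int] = {}
        h = 0
        for i, el in enumerate(self.atoms):
            counts[el] = counts.get(el, 0) + 1
            if el != "H":
                h += self.implicit_hydrogens(i)
        if h:
            counts["H"] = counts.get("H", 0) + h
        return counts

    def relabel(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atom *i* moved to position ``perm[i]``."""
        n = self.n_atoms
        atoms = [""] * n
        for i, el in enumerate(self.atoms):
            atoms[perm[i]] = el
        bonds = {}
        for (i, j), order in self.bonds.items():
            a, b = perm[i], perm[j]
            bonds[(min(a, b), max(a, b))] = order
        return MolecularGraph(tuple(atoms), bonds)


# ---------------------------------------------------------------------------
# Canonical labeling: partition refinement + backtracking max-serialization
# ---------------------------------------------------------------------------


def _refine(mol: MolecularGraph, cells: List[List[int]]) -> List[List[int]]:
    """Equitable refinement of an ordered partition.

    Atoms are repeatedly split by the multiset of (bond order, neighbor
    cell) pairs; sub-cells are ordered by their (invariant) signature so
    the resulting ordered partition is identical for isomorphic graphs.
    """
    adj = mol.adjacency_matrix()
    n = mol.n_atoms
    while True:
        cell_of = [0] * n
        for ci, cell in enumerate(cells):
            for a in cell:
                cell_of[a] = ci
        new_cells: List[List[int]] = []
        changed = False
        for cell in cells:
            if len(cell) == 1:
                new_cells.append(cell)
                continue
            sig = {}
            for a in cell:
                s = tuple(sorted((adj[a][b], cell_of[b]) for b in range(n) if adj[a][b]))
                sig.setdefault(s, []).append(a)
            if len(sig) == 1:
                new_cells.append(cell)
            else:
                changed = True
                for s in sorted(sig):
                    new_cells.append(sorted(sig[s]))
        cells = new_cells
        if not changed:
            return cells


def _initial_cells(mol: MolecularGraph) -> List[List[int]]:
    by_el: Dict[str, List[int]] = {}
    for i, el in enumerate(mol.atoms):
        by_el.setdefault(el, []).append(i)
    return [by_el[el] for el in sorted(by_el)]


def canonical_order(mol: MolecularGraph) -> Tuple[Tuple[int, ...], List[Tuple[int, ...]]]:
    """Canonical labeling and all optimal labelings of *mol*.

    Returns ``(labeling, all_labelings)`` where ``labeling`` maps
    position -> atom index and ``all_labelings`` contains every
    labeling attaining the lexicographically maximal serialization
    (their pairwise composition yields the automorphism group).
    """
    n = mol.n_atoms
    if n == 0:
        return (), [()]
    cells = _refine(mol, _initial_cells(mol))
    adj = mol.adjacency_matrix()
    # Position k belongs to cell block `block_of[k]` (blocks contiguous).
    block_of: List[int] = []
    for ci, cell in enumerate(cells):
        block_of.extend([ci] * len(cell))

    best_rows: List[Tuple[int, ...]] | None = None
    best_labelings: List[Tuple[int, ...]] = []

    placed: List[int] = []
    used = [False] * n
    rows: List[Tuple[int, ...]] = []

    def rec(k: int):
        nonlocal best_rows
        if best_rows is not None:
            # Prefix comparison against the incumbent optimum.
            if rows < best_rows[:k]:
                return
        if k == n:
            if best_rows is None or rows > best_rows:
                best_rows = list(rows)
                best_labelings.clear()
                best_labelings.append(tuple(placed))
            elif rows == best_rows:
                best_labelings.append(tuple(placed))
            return
        cell = cells[block_of[k]]
        scored = [
            (tuple(adj[a][p] for p in placed), a) for a in cell if not used[a]
        ]
        mx = max(s for s, _ in scored)
        for s, a in scored:
            if s != mx:
                continue
            placed.append(a)
            used[a] = True
            rows.append(s)
            rec(k + 1)
            rows.pop()
            placed.pop()
            used[a] = False

    rec(0)
    # All labelings in best_labelings attain the same maximal row sequence.
    return best_labelings[0], best_labelings


def canonical_form(mol: MolecularGraph) -> str:
    """Certificate: identical for isomorphic graphs, distinct otherwise.

    Serialized as the element sequence in canonical position order plus
    the lexicographically maximal lower-triangular bond-order rows.
    """
    mol.validate()
    labeling, _ = canonical_order(mol)
    adj = mol.adjacency_matrix()
    elements = ".".join(mol.atoms[a] for a in labeling)
    rows = []
    for k, a in enumerate(labeling):
        rows.append("".join(str(adj[a][labeling[j]]) for j in range(k)))
    return elements + "|" + ",".join(rows)


def are_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    if sorted(a.atoms) != sorted(b.atoms):
        return False
    if sorted(a.bonds.values()) != sorted(b.bonds.values()):
        return False
    return canonical_form(a) == canonical_form(b)


def automorphism_group(mol: MolecularGraph) -> List[Tuple[int, ...]]:
    """All atom permutations preserving elements and bond orders.

    Returned as tuples ``sigma`` with ``sigma[i]`` the image of atom
    ``i``; contains the identity and is closed under composition.
    """
    _, labelings = canonical_order(mol)
    ref = labelings[0]
    n = mol.n_atoms
    group = []
    for lab in labelings:
        sigma = [0] * n
        for k in range(n):
            sigma[ref[k]] = lab[k]
        group.append(tuple(sigma))
    return group


def add_implicit_hydrogens(mol: MolecularGraph) -> MolecularGraph:
    """Materialize implicit hydrogens as explicit H atoms."""
    atoms = list(mol.atoms)
    bonds = dict(mol.bonds)
    for i, el in enumerate(mol.atoms):
        if el == "H":
            continue
        h = mol.implicit_hydrogens(i)
        if h < 0:
            raise ValenceError(f"atom {i} ({el}) is over-valent", i)
        for _ in range(h):
            atoms.append("H")
            bonds[(i, len(atoms) - 1)] = 1
    return MolecularGraph(tuple(atoms), bonds)


# ---------------------------------------------------------------------------
# SMILES subset I/O (Kekulé only; placeholder written as ``B`` by default)
# ---------------------------------------------------------------------------

_BOND_CHAR = {1: "", 2: "=", 3: "#"}
_CHAR_BOND = {"-": 1, "=": 2, "#": 3}


def to_smiles(mol: MolecularGraph, placeholder_token: str = PLACEHOLDER) -> str:
    """Write a canonical-order Kekulé SMILES (subset dialect).

    Atom ordering follows the canonical labeling, so isomorphic graphs
    serialize identically — the SMILES doubles as a readable certificate.
    """
    mol.validate()
    n = mol.n_atoms
    if n == 0:
        return ""
    labeling, _ = canonical_order(mol)
    pos = {a: k for k, a in enumerate(labeling)}
    adj = mol.adjacency_matrix()

    # DFS over canonical positions; ring-closure digits for back edges.
    visited = [False] * n
    ring_bonds: Dict[Tuple[int, int], int] = {}
    ring_counter = [0]
    open_digits: Dict[Tuple[int, int], int] = {}

    def atom_token(a: int) -> str:
        el = mol.atoms[a]
        if el == "H":
            return "[H]"
        if el == PLACEHOLDER:
            return placeholder_token
        return el

    def dfs(a: int, parent: int) -> str:
        visited[a] = True
        out = [atom_token(a)]
        nbrs = sorted(
            ((pos[b], b, order) for b, order in mol.neighbors(a) if b != parent),
            key=lambda t: t[0],
        )
        # Ring closures first: back edges to already-visited atoms.
        tails = []
        for _, b, order in nbrs:
            key = (min(a, b), max(a, b))
            if visited[b]:
                if key in open_digits:
                    out.append(_BOND_CHAR[order] + _digit(open_digits.pop(key)))
                else:
                    ring_counter[0] += 1
                    open_digits[key] = ring_counter[0]
                    out.append(_BOND_CHAR[order] + _digit(ring_counter[0]))
            else:
                tails.append((b, order))
        for idx, (b, order) in enumerate(tails):
            if visited[b]:  # became visited through an earlier branch: ring bond
                key = (min(a, b), max(a, b))
                if key in open_digits:
                    out.append(_BOND_CHAR[order] + _digit(open_digits.pop(key)))
                else:
                    ring_counter[0] += 1
                    open_digits[key] = ring_counter[0]
                    out.append(_BOND_CHAR[order] + _digit(ring_counter[0]))
                continue
            sub = _BOND_CHAR[order] + dfs(b, a)
            if idx < len(tails) - 1:
                out.append("(" + sub + ")")
            else:
                out.append(sub)
        return "".join(out)

    def _digit(d: int) -> str:
        return str(d) if d <= 9 else f"%{d:02d}"

    return dfs(labeling[0], -1)


def from_smiles(text: str, placeholder_token: str = PLACEHOLDER) -> MolecularGraph:
    """Parse the SMILES subset: C/N/O/S/H + placeholder, bonds -,=,#,
    branches, ring closures.  Lowercase aromatic atoms are rejected —
    aromatic rings must be written in Kekulé form."""
    atoms: List[str] = []
    bonds: Dict[Tuple[int, int], int] = {}
    stack: List[int] = []
    prev = -1
    pending_order = 1
    ring_open: Dict[int, Tuple[int, int]] = {}
    i = 0
    n_text = len(text)

    def add_bond(a: int, b: int, order: int):
        key = (min(a, b), max(a, b))
        if key in bonds:
            raise ValueError(f"duplicate bond between atoms {a} and {b}")
        bonds[key] = order

    def add_atom(el: str) -> None:
        nonlocal prev, pending_order
        atoms.append(el)
        idx = len(atoms) - 1
        if prev >= 0:
            add_bond(prev, idx, pending_order)
        prev = idx
        pending_order = 1

    while i < n_text:
        ch = text[i]
        if ch in "CNOSH" or (placeholder_token and text.startswith(placeholder_token, i) and placeholder_token[0].isupper()):
            if text.startswith(placeholder_token, i) and placeholder_token not in ("C", "N", "O", "S", "H"):
                add_atom(PLACEHOLDER)
                i += len(placeholder_token)
            else:
                add_atom(ch)
                i += 1
        elif ch == "[":
            j = text.index("]", i)
            inner = text[i + 1 : j]
            # strip an explicit H count (validated implicitly by valence)
            core = inner
            if "H" in inner[1:]:
                core = inner[: 1 + inner[1:].index("H")]
            if core == placeholder_token or core == PLACEHOLDER:
                add_atom(PLACEHOLDER)
            elif core in ("C", "N", "O", "S", "H"):
                add_atom(core)
            else:
                raise ValueError(f"unsupported bracket atom [{inner}] at position {i}")
            i = j + 1
        elif ch in "-=#":
            pending_order = _CHAR_BOND[ch]
            i += 1
        elif ch == "(":
            stack.append(prev)
            i += 1
        elif ch == ")":
            prev = stack.pop()
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                d = int(text[i + 1 : i + 3])
                i += 3
            else:
                d = int(ch)
                i += 1
            if d in ring_open:
                a, order_open = ring_open.pop(d)
                order = max(order_open, pending_order)
                add_bond(a, prev, order)
                pending_order = 1
            else:
                ring_open[d] = (prev, pending_order)
                pending_order = 1
        elif ch in "acbnosp":
            raise ValueError(
                f"aromatic atom {ch!r} at position {i}: Kekulé SMILES required"
            )
        else:
            raise ValueError(f"unsupported SMILES token {ch!r} at position {i}")
    if ring_open:
        raise ValueError(f"unclosed ring bond(s): {sorted(ring_open)}")
    mol = MolecularGraph(tuple(atoms), bonds)
    mol.validate()
    return mol


def to_molblock(mol: MolecularGraph, name: str = "") -> str:
    """MOL V2000 text block (explicit hydrogens, no coordinates)."""
    full = add_implicit_hydrogens(mol)
    lines = [name, "  isospace", ""]
    lines.append(
        f"{full.n_atoms:>3d}{len(full.bonds):>3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for el in full.atoms:
        sym = "R" if el == PLACEHOLDER else el
        lines.append(f"    0.0000    0.0000    0.0000 {sym:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for (i, j), order in sorted(full.bonds.items()):
        lines.append(f"{i + 1:>3d}{j + 1:>3d}{order:>3d}  0  0  0  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"
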