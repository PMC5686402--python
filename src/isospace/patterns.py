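"""Substructure patterns for badlist/goodlist filtering.

Patterns are written in a small SMARTS-like dialect:

* element symbols ``C N O S B`` (``B`` the univalent placeholder) and
  the wildcard ``*`` matching any element;
* bond symbols ``-`` ``=`` ``#`` and ``~`` (any order); a bare
  juxtaposition means a single bond, as in SMILES;
* branches ``( )`` and single-digit ring closures;
* bracket atoms ``[OH]`` / ``[NH2]`` requiring a *minimum* implicit
  hydrogen count on the matched atom (``[OH]`` = oxygen carrying at
  least one hydrogen); ``[*]`` is the bracketed wildcard.

Anything beyond this subset (aromatic primitives, charges, recursive
SMARTS, logical operators, other elements) is rejected loudly.

Matching is plain label- and bond-order-consistent subgraph embedding
(injective), implemented as a backtracking search.  A pattern may
additionally demand that every matched atom's free valence is satisfied
by hydrogens only (``implicit_h_satisfied``), i.e. the molecule atom
has no heavy neighbors outside the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chemgraph import VALENCES, MolecularGraph

__all__ = [
    "SubstructurePattern",
    "Badlist",
    "FilterReport",
    "parse_pattern",
    "match",
    "count_embeddings",
    "filter_library",
    "load_badlist",
]

_ANY = None  # bond order wildcard


@dataclass(frozen=True)
class SubstructurePattern:
    """Connected pattern graph with element/bond wildcards."""

    atoms: Tuple[Tuple[str, int], ...]  # (element or "*", min implicit H)
    bonds: Tuple[Tuple[int, int, Optional[int]], ...]  # (i, j, order|None)
    implicit_h_satisfied: bool = False
    source: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))

    def neighbors(self, i: int) -> List[Tuple[int, Optional[int]]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def __str__(self) -> str:
        return self.source or f"<pattern {self.n_atoms} atoms>"


def parse_pattern(text: str, implicit_h_satisfied: bool = False) -> SubstructurePattern:
    """Parse the SMARTS-subset dialect described in the module docstring."""
    src = text.strip()
    atoms: List[Tuple[str, int]] = []
    bonds: List[Tuple[int, int, Optional[int]]] = []
    stack: List[int] = []
    ring_open: Dict[int, Tuple[int, object]] = {}
    prev = -1
    pending: object = 1
    pending_set = False
    i = 0

    def add_atom(el: str, min_h: int):
        nonlocal prev, pending, pending_set
        atoms.append((el, min_h))
        idx = len(atoms) - 1
        if prev >= 0:
            bonds.append((prev, idx, pending))
        prev = idx
        pending = 1
        pending_set = False

    while i < len(src):
        ch = src[i]
        if ch in "CNOSB":
            add_atom(ch, 0)
            i += 1
        elif ch == "*":
            add_atom("*", 0)
            i += 1
        elif ch == "[":
            j = src.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket at position {i} in {src!r}")
            inner = src[i + 1 : j]
            el, min_h = _parse_bracket(inner, i)
            add_atom(el, min_h)
            i = j + 1
        elif ch == "-":
            pending, pending_set = 1, True
            i += 1
        elif ch == "=":
            pending, pending_set = 2, True
            i += 1
        elif ch == "#":
            pending, pending_set = 3, True
            i += 1
        elif ch == "~":
            pending, pending_set = _ANY, True
            i += 1
        elif ch == "(":
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i} in {src!r}")
            prev = stack.pop()
            i += 1
        elif ch.isdigit():
            d = int(ch)
            if d in ring_open:
                a, order_open = ring_open.pop(d)
                order = pending if pending_set else order_open
                bonds.append((a, prev, order))
                pending, pending_set = 1, False
            else:
                ring_open[d] = (prev, pending if pending_set else 1)
                pending, pending_set = 1, False
            i += 1
        elif ch.islower():
            raise ValueError(
                f"unsupported token {ch!r} at position {i} in {src!r} "
                "(aromatic primitives are outside the supported subset)"
            )
        else:
            raise ValueError(f"unsupported token {ch!r} at position {i} in {src!r}")
    if ring_open:
        raise ValueError(f"unclosed ring closure(s) {sorted(ring_open)} in {src!r}")
    if not atoms:
        raise ValueError("empty pattern")
    pat = SubstructurePattern(
        tuple(atoms), tuple(bonds), implicit_h_satisfied, src
    )
    _check_connected(pat)
    return pat


def _parse_bracket(inner: str, pos: int) -> Tuple[str, int]:
    if not inner:
        raise ValueError(f"empty bracket at position {pos}")
    if inner[0] == "*":
        el, rest = "*", inner[1:]
    else:
        # element symbol: one uppercase + optional lowercase
        k = 1
        while k < len(inner) and inner[k].islower():
            k += 1
        el, rest = inner[:k], inner[k:]
        if el not in ("C", "N", "O", "S", "B"):
            raise ValueError(
                f"unsupported element [{inner}] at position {pos}: "
                f"{el!r} is outside the supported subset"
            )
    min_h = 0
    if rest:
        if rest[0] != "H":
            raise ValueError(f"unsupported bracket content [{inner}] at position {pos}")
        digits = rest[1:]
        if digits and not digits.isdigit():
            raise ValueError(f"unsupported bracket content [{inner}] at position {pos}")
        min_h = int(digits) if digits else 1
    return el, min_h


def _check_connected(p: SubstructurePattern) -> None:
    if p.n_atoms == 1:
        return
    adj: Dict[int, List[int]] = {i: [] for i in range(p.n_atoms)}
    for a, b, _ in p.bonds:
        adj[a].append(b)
        adj[b].append(a)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != p.n_atoms:
        raise ValueError(f"pattern {p.source!r} is not connected")


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _embeddings(p: SubstructurePattern, mol: MolecularGraph, first_only: bool):
    """Backtracking injective embeddings pattern -> molecule."""
    n_p = p.n_atoms
    # DFS order over the connected pattern keeps candidates constrained.
    order: List[int] = [0]
    seen = {0}
    while len(order) < n_p:
        advanced = False
        for a in list(order):
            for b, _ in p.neighbors(a):
                if b not in seen:
                    order.append(b)
                    seen.add(b)
                    advanced = True
                    break
            if advanced:
                break
    adj = mol.adjacency_matrix()
    heavy_deg = [mol.heavy_degree(i) for i in range(mol.n_atoms)]
    imp_h = [mol.implicit_hydrogens(i) for i in range(mol.n_atoms)]

    mapping: Dict[int, int] = {}
    used = [False] * mol.n_atoms
    results: List[Dict[int, int]] = []

    def compatible(pa: int, ma: int) -> bool:
        el, min_h = p.atoms[pa]
        if el != "*" and mol.atoms[ma] != el:
            return False
        if imp_h[ma] < min_h:
            return False
        if heavy_deg[ma] < p.degree(pa):
            return False
        if p.implicit_h_satisfied and heavy_deg[ma] != p.degree(pa):
            return False
        return True

    def rec(k: int) -> bool:
        if k == n_p:
            results.append(dict(mapping))
            return first_only
        pa = order[k]
        anchors = [
            (pb, bo) for pb, bo in p.neighbors(pa) if pb in mapping
        ]
        if anchors:
            pb0, bo0 = anchors[0]
            cands = [
                mb
                for mb, mo in mol.neighbors(mapping[pb0])
                if not used[mb] and (bo0 is _ANY or mo == bo0)
            ]
        else:
            cands = [m for m in range(mol.n_atoms) if not used[m]]
        for ma in cands:
            if not compatible(pa, ma):
                continue
            ok = True
            for pb, bo in anchors:
                mo = adj[mapping[pb]][ma]
                if mo == 0 or (bo is not _ANY and mo != bo):
                    ok = False
                    break
            if not ok:
                continue
            mapping[pa] = ma
            used[ma] = True
            if rec(k + 1):
                return True
            del mapping[pa]
            used[ma] = False
        return False

    rec(0)
    return results


def embeddings(p: SubstructurePattern, mol: MolecularGraph) -> List[Dict[int, int]]:
    """All injective embeddings as pattern-index -> molecule-index maps."""
    return _embeddings(p, mol, first_only=False)


def match(p: SubstructurePattern, mol: MolecularGraph) -> bool:
    """True iff *p* embeds somewhere in *mol*."""
    return bool(_embeddings(p, mol, first_only=True))


def count_embeddings(p: SubstructurePattern, mol: MolecularGraph) -> int:
    """Number of injective embeddings (labelled, not orbit-reduced)."""
    return len(_embeddings(p, mol, first_only=False))


# ---------------------------------------------------------------------------
# Badlists and library filtering
# ---------------------------------------------------------------------------


@dataclass
class Badlist:
    """Named ordered list of forbidden substructures with rationales."""

    name: str
    entries: List[Tuple[str, SubstructurePattern, str]] = field(default_factory=list)

    def add(self, name: str, pattern: SubstructurePattern, rationale: str = ""):
        if any(n == name for n, _, _ in self.entries):
            raise ValueError(f"duplicate pattern name {name!r}")
        self.entries.append((name, pattern, rationale))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def patterns(self) -> List[SubstructurePattern]:
        return [p for _, p, _ in self.entries]


@dataclass
class FilterReport:
    """Removal accounting: first-match attribution per badlist pattern."""

    total_in: int = 0
    total_removed_bad: int = 0
    total_removed_good: int = 0
    removed_by: Dict[str, int] = field(default_factory=dict)

    @property
    def total_out(self) -> int:
        return self.total_in - self.total_removed_bad - self.total_removed_good

    def to_tsv(self) -> str:
        lines = ["pattern\tremoved"]
        for name, count in self.removed_by.items():
            lines.append(f"{name}\t{count}")
        lines.append(f"(goodlist)\t{self.total_removed_good}")
        lines.append(f"(total removed)\t{self.total_removed_bad + self.total_removed_good}")
        return "\n".join(lines) + "\n"


def filter_library(
    mols: Iterable[MolecularGraph],
    bad: Badlist | None = None,
    good: Sequence[SubstructurePattern] = (),
) -> Tuple[List[MolecularGraph], FilterReport]:
    """Keep molecules matching no bad pattern and every good pattern.

    A molecule removed by several bad patterns is attributed to the
    earliest one in the list (first-match attribution), so the per-
    pattern counts sum to the total removed.
    """
    report = FilterReport()
    if bad is not None:
        for name, _, _ in bad:
            report.removed_by[name] = 0
    out: List[MolecularGraph] = []
    for mol in mols:
        report.total_in += 1
        hit = None
        if bad is not None:
            for name, pattern, _ in bad:
                if match(pattern, mol):
                    hit = name
                    break
        if hit is not None:
            report.removed_by[hit] += 1
            report.total_removed_bad += 1
            continue
        if any(not match(g, mol) for g in good):
            report.total_removed_good += 1
            continue
        out.append(mol)
    return out, report


def load_badlist(path, name: str | None = None) -> Badlist:
    """Read a badlist file: one pattern per line, ``#`` comments carry
    the rationale; blank lines ignored.  Pattern names default to the
    pattern text (suffixed when repeated)."""
    import os

    bl = Badlist(name or os.path.basename(str(path)))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "#" in line:
                pat_text, rationale = line.split("#", 1)
            else:
                pat_text, rationale = line, ""
            pat_text = pat_text.strip()
            try:
                pattern = parse_pattern(pat_text)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            pname = pat_text
            k = 2
            while any(n == pname for n, _, _ in bl.entries):
                pname = f"{pat_text}#{k}"
                k += 1
            bl.add(pname, pattern, rationale.strip())
    return bl
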