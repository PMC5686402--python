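"""Complete, non-redundant enumeration of constitutional isomers.

Given an exact molecular formula, every connected multigraph satisfying
the fixed valences is produced exactly once.  The search fills the
upper triangle of a bond-order matrix row by row over a fixed atom
order (elements sorted by decreasing valence), so that all bonds of
atom *i* are decided when row *i* closes.  Three sound prunes keep the
search near the size of the isomorphism-class count:

* residual-valence and bond-budget bounds (each atom's incident order
  can never exceed its valence; the total bond order is fixed by the
  hydrogen count);
* connectivity look-ahead (a finished component that excludes later
  atoms can never be completed into a connected molecule);
* an adjacent-transposition semicanonicity test — a necessary
  condition for the matrix to be the lexicographically maximal
  representative of its class under element-preserving relabelings.

Residual duplicates (from symmetries the transposition test cannot
see) are removed at emission by certificate, which also fixes the
deterministic output order: lexicographic by certificate.

``brute_force_enumerate`` is a deliberately naive re-implementation —
nested assignment over all atom pairs with only valence bookkeeping —
kept as an in-package oracle for exhaustive cross-checks at small
sizes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

from .chemgraph import MolecularGraph, canonical_form, valence
from .formula import Formula, is_graphical
from .patterns import Badlist, SubstructurePattern, match

__all__ = [
    "GenerationConstraints",
    "GenerationRun",
    "enumerate_isomers",
    "count_isomers",
    "brute_force_enumerate",
    "generate",
]


@dataclass
class GenerationConstraints:
    """Structural constraints applied during generation."""

    badlist: Optional[Badlist] = None
    goodlist: Sequence[SubstructurePattern] = ()
    max_ring_size: Optional[int] = None

    def __post_init__(self):
        if self.max_ring_size is not None and self.max_ring_size < 3:
            raise ValueError("max_ring_size must be >= 3")

    def passes(self, mol: MolecularGraph) -> bool:
        if self.badlist is not None and any(
            match(p, mol) for p in self.badlist.patterns()
        ):
            return False
        if any(not match(g, mol) for g in self.goodlist):
            return False
        if self.max_ring_size is not None and _max_ring(mol) > self.max_ring_size:
            return False
        return True


@dataclass
class GenerationRun:
    """Statistics of one enumeration call."""

    formula: str = ""
    emitted: int = 0
    pruned_by_canonicity: int = 0
    pruned_by_constraints: int = 0
    wall_time: float = 0.0


def _max_ring(mol: MolecularGraph) -> int:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from(mol.bonds)
    basis = nx.minimum_cycle_basis(g)
    return max((len(c) for c in basis), default=0)


def _search(formula: Formula) -> Iterator[Tuple[str, MolecularGraph]]:
    """Yield (certificate, graph) for each isomorphism class, unsorted.

    May yield the same class at most once (duplicates suppressed by a
    certificate set held for the run).
    """
    elements = formula.heavy_atoms()
    n = len(elements)
    vals = [valence(e) for e in elements]
    n_h = formula["H"]
    total_order = (sum(vals) - n_h) // 2

    if n == 1:
        mol = MolecularGraph((elements[0],), {})
        yield canonical_form(mol), mol
        return

    adj = [[0] * n for _ in range(n)]
    nbrs: List[List[int]] = [[] for _ in range(n)]
    resid = vals[:]
    seen: Set[str] = set()
    placed = [0]  # running total bond order, boxed for closures
    resid_sum = [sum(vals)]
    frozen = [0]  # residual valence of closed rows (becomes hydrogens)

    def components_ok(i: int) -> bool:
        # All bonds of atoms 0..i are final; any component fully inside
        # 0..i that misses atoms dooms connectivity.
        done = [False] * (i + 1)
        for start in range(i + 1):
            if done[start]:
                continue
            comp = {start}
            done[start] = True
            stack = [start]
            touches_future = False
            while stack:
                for b in nbrs[stack.pop()]:
                    if b not in comp:
                        comp.add(b)
                        if b > i:
                            touches_future = True
                        else:
                            done[b] = True
                            stack.append(b)
            if not touches_future and len(comp) < n:
                return False
        return True

    def semicanonical_ok(i: int) -> bool:
        # Necessary condition of lex-max: swapping same-element atoms
        # i-1 and i must not increase the serialized matrix.
        if i == 0 or elements[i - 1] != elements[i]:
            return True
        col_prev = adj[i - 1]
        col_cur = adj[i]
        for k in range(i - 1):
            if col_prev[k] != col_cur[k]:
                return col_prev[k] > col_cur[k]
        return col_prev[i + 1 :] >= col_cur[i + 1 :]

    def fill_row(i: int, j: int):
        if j == n:
            if not semicanonical_ok(i) or not components_ok(i):
                return
            if i == n - 2:
                # Last row (n-1) has no columns; finish here.
                if placed[0] == total_order:
                    yield from emit()
                return
            frozen[0] += resid[i]
            yield from fill_row(i + 1, i + 2)
            frozen[0] -= resid[i]
            return
        row_i = adj[i]
        for order in range(min(3, resid[i], resid[j]), -1, -1):
            new_placed = placed[0] + order
            if new_placed > total_order:
                continue
            resid[i] -= order
            resid[j] -= order
            resid_sum[0] -= 2 * order
            # Upper bound on future placeable order: every further bond
            # drains two units of residual valence, and rows < i are
            # closed (their residuals are frozen as hydrogens).
            if new_placed + (resid_sum[0] - frozen[0]) // 2 >= total_order:
                if order:
                    row_i[j] = adj[j][i] = order
                    nbrs[i].append(j)
                    nbrs[j].append(i)
                    placed[0] = new_placed
                    yield from fill_row(i, j + 1)
                    placed[0] = new_placed - order
                    nbrs[i].pop()
                    nbrs[j].pop()
                    row_i[j] = adj[j][i] = 0
                else:
                    yield from fill_row(i, j + 1)
            resid[i] += order
            resid[j] += order
            resid_sum[0] += 2 * order

    def emit():
        bonds = {}
        for a in range(n):
            row = adj[a]
            for b in range(a + 1, n):
                if row[b]:
                    bonds[(a, b)] = row[b]
        mol = MolecularGraph(tuple(elements), bonds)
        if not mol.is_connected():
            return
        cert = canonical_form(mol)
        if cert in seen:
            return
        seen.add(cert)
        yield cert, mol

    if n >= 2:
        yield from fill_row(0, 1)


def enumerate_isomers(
    formula: Formula,
    constraints: Optional[GenerationConstraints] = None,
    stats: Optional[GenerationRun] = None,
) -> Iterator[MolecularGraph]:
    """Every connected constitutional isomer of *formula* passing
    *constraints*, each exactly once, in lexicographic certificate
    order.  A non-graphical formula yields an empty stream."""
    t0 = time.monotonic()
    if stats is not None:
        stats.formula = str(formula)
    if not is_graphical(formula):
        import warnings

        warnings.warn(f"formula {formula} is not graphical; empty stream")
        if stats is not None:
            stats.wall_time = time.monotonic() - t0
        return
    constraints = constraints or GenerationConstraints()
    kept: List[Tuple[str, MolecularGraph]] = []
    for cert, mol in _search(formula):
        if constraints.passes(mol):
            kept.append((cert, mol))
        elif stats is not None:
            stats.pruned_by_constraints += 1
    kept.sort(key=lambda t: t[0])
    if stats is not None:
        stats.emitted = len(kept)
        stats.wall_time = time.monotonic() - t0
    for _, mol in kept:
        yield mol


def count_isomers(
    formula: Formula, constraints: Optional[GenerationConstraints] = None
) -> int:
    """Number of constraint-passing isomers (structures not retained)."""
    if not is_graphical(formula):
        return 0
    constraints = constraints or GenerationConstraints()
    n = 0
    for _, mol in _search(formula):
        if constraints.passes(mol):
            n += 1
    return n


def generate(
    formula: Formula, constraints: Optional[GenerationConstraints] = None
) -> Tuple[List[MolecularGraph], GenerationRun]:
    """Materialized enumeration plus run statistics."""
    stats = GenerationRun()
    mols = list(enumerate_isomers(formula, constraints, stats))
    return mols, stats


def brute_force_enumerate(formula: Formula, max_heavy: int = 7) -> Set[str]:
    """Certificate set by exhaustive bond-matrix assignment (oracle).

    Enumerates every symmetric bond-order matrix over all atom pairs
    with only valence bookkeeping, keeps connected graphs, dedupes by
    certificate.  Exponential; refuses more than *max_heavy* heavy
    atoms.  Used in tests as an independent check of the pruned search.
    """
    elements = formula.heavy_atoms()
    n = len(elements)
    if n > max_heavy:
        raise ValueError(f"{n} heavy atoms exceeds brute-force cap {max_heavy}")
    vals = [valence(e) for e in elements]
    n_h = formula["H"]
    if (sum(vals) - n_h) % 2 or sum(vals) < n_h:
        return set()
    total_order = (sum(vals) - n_h) // 2
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    certs: Set[str] = set()
    if n == 1:
        if n_h == vals[0]:
            certs.add(canonical_form(MolecularGraph((elements[0],), {})))
        return certs
    resid = vals[:]
    bonds: Dict[Tuple[int, int], int] = {}

    def rec(k: int, placed: int):
        if placed > total_order:
            return
        if k == len(pairs):
            if placed != total_order:
                return
            mol = MolecularGraph(tuple(elements), dict(bonds))
            if mol.is_connected():
                certs.add(canonical_form(mol))
            return
        i, j = pairs[k]
        for order in range(0, min(3, resid[i], resid[j]) + 1):
            if order:
                bonds[(i, j)] = order
                resid[i] -= order
                resid[j] -= order
            rec(k + 1, placed + order)
            if order:
                del bonds[(i, j)]
                resid[i] += order
                resid[j] += order

    rec(0, 0)
    return certs
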