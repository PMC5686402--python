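"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from isospace.chemgraph import MolecularGraph, valence
from isospace.formula import Formula
from isospace.generator import _search


def igraph_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Independent isomorphism oracle: igraph VF2 with vertex and edge
    colors (element labels and bond orders)."""
    import igraph

    if sorted(a.atoms) != sorted(b.atoms):
        return False
    elements = sorted(set(a.atoms) | set(b.atoms))

    def build(m: MolecularGraph):
        g = igraph.Graph(n=m.n_atoms)
        edges, colors = [], []
        for (i, j), order in m.bonds.items():
            edges.append((i, j))
            colors.append(order)
        g.add_edges(edges)
        vc = [elements.index(el) for el in m.atoms]
        return g, vc, colors

    ga, vca, eca = build(a)
    gb, vcb, ecb = build(b)
    return ga.isomorphic_vf2(
        gb, color1=vca, color2=vcb, edge_color1=eca, edge_color2=ecb
    )


def exhaustive_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Brute-force isomorphism by trying every label-preserving
    permutation (only for tiny graphs)."""
    n = a.n_atoms
    if n != b.n_atoms or sorted(a.atoms) != sorted(b.atoms):
        return False
    adj_a = a.adjacency_matrix()
    adj_b = b.adjacency_matrix()
    for perm in itertools.permutations(range(n)):
        if any(a.atoms[i] != b.atoms[perm[i]] for i in range(n)):
            continue
        if all(
            adj_a[i][j] == adj_b[perm[i]][perm[j]]
            for i in range(n)
            for j in range(i + 1, n)
        ):
            return True
    return False


def random_molecule(rng: random.Random, max_atoms: int = 7) -> MolecularGraph:
    """Random connected valence-respecting molecular graph."""
    n = rng.randint(1, max_atoms)
    atoms = [rng.choice(["C", "C", "N", "O", "S"]) for _ in range(n)]
    resid = [valence(el) for el in atoms]
    bonds = {}
    order_pool = [1, 1, 1, 2, 3]
    # random spanning tree first
    nodes = list(range(n))
    rng.shuffle(nodes)
    for k in range(1, n):
        a = nodes[k]
        anchors = [b for b in nodes[:k] if resid[b] >= 1]
        if not anchors:
            return random_molecule(rng, max_atoms)
        b = rng.choice(anchors)
        o = min(rng.choice(order_pool), resid[a], resid[b])
        bonds[(min(a, b), max(a, b))] = o
        resid[a] -= o
        resid[b] -= o
    # a few random extra bonds
    for _ in range(rng.randint(0, 2)):
        cand = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in bonds and resid[i] >= 1 and resid[j] >= 1
        ]
        if not cand:
            break
        i, j = rng.choice(cand)
        o = min(rng.choice(order_pool), resid[i], resid[j])
        bonds[(i, j)] = o
        resid[i] -= o
        resid[j] -= o
    return MolecularGraph(tuple(atoms), bonds)


def relabel_randomly(mol: MolecularGraph, rng: random.Random) -> MolecularGraph:
    perm = list(range(mol.n_atoms))
    rng.shuffle(perm)
    return mol.relabel(perm)


@pytest.fixture(scope="session")
def riboside_raw():
    """All 32 710 raw constitutional isomers of C5H9O4B (shared across
    the acceptance-level tests; one ~3 min enumeration per session)."""
    f = Formula({"C": 5, "H": 9, "O": 4, "B": 1})
    return [mol for _, mol in _search(f)]
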