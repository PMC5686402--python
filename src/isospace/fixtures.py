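"""Deterministic test-fixture profiles.

Small, seeded inputs used by the test suite and the examples: formula
lists with oracle counts, toy libraries with hand-resolvable
properties, and a synthetic adaptive-analysis library with a planted
dominating subpopulation whose better-set probability has a closed
form.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .chemgraph import from_smiles
from .formula import Formula, FuzzyFormula, expand_fuzzy
from .generator import brute_force_enumerate
from .libraries import Library, free_functional_groups

__all__ = ["fixture_generator", "planted_better_probability", "PROFILES"]

PROFILES = (
    "tiny-formulae",
    "toy-amino-acids",
    "toy-nucleosides",
    "adaptive-synthetic",
)


def _tiny_formulae(seed: int) -> List[Tuple[str, int]]:
    """All graphical CHNO formulae with <= 4 heavy atoms, with oracle
    isomer counts from the brute-force enumerator."""
    out = []
    space = FuzzyFormula({"C": (0, 4), "N": (0, 4), "O": (0, 4)})
    for f in expand_fuzzy(space, cap=100_000):
        if f.n_heavy <= 4:
            out.append((str(f), len(brute_force_enumerate(f))))
    return out


def _toy_amino_acids(seed: int) -> Library:
    lib = Library("toy-amino-acids", provenance={"profile": "toy-amino-acids"})
    for smi, name in [
        ("NCC(=O)O", "glycine"),
        ("CC(N)C(=O)O", "alanine"),
        ("OCC(N)C(=O)O", "serine"),
        ("NC(CS)C(=O)O", "cysteine"),
        ("OC(=O)CC(N)C(=O)O", "aspartate"),
        ("CCC(N)C(=O)O", "2-aminobutyric acid"),
    ]:
        lib.add(from_smiles(smi), name=name)
    return lib


def _toy_nucleosides(seed: int) -> List[Tuple[str, int]]:
    """Small placeholder-bearing molecules with hand-counted free
    functional groups (O-H/N-H sites away from the placeholder)."""
    cases = [
        ("BCO", 1),  # B-CH2-OH
        ("BOCCO", 1),  # B-O-CH2-CH2-OH: the B-bonded O does not count
        ("BC(O)CO", 2),  # B-CH(OH)-CH2-OH
        ("BC(N)CO", 2),  # amino + hydroxyl
        ("BCC", 0),  # no heteroatoms
        ("BC1CCO1", 0),  # ring ether: no free O-H
    ]
    for smi, expected in cases:
        assert free_functional_groups(from_smiles(smi)) == expected, smi
    return cases


def _adaptive_synthetic(
    seed: int, n_library: int = 200, n_high: int = 20, set_size: int = 20
) -> Dict:
    """Planted-dominance synthetic property table.

    Axis ``logp`` takes three values: 0 and 1 for ordinary members and
    10 for a planted 'extreme' subpopulation of ``n_high`` members;
    ``vdw_volume`` and ``pka`` are constant, so range/evenness tie on
    them for every set.  The reference alphabet holds ten 0s and ten
    1s (range 1, evenness 0).  A random set strictly dominates the
    reference iff it contains at least one extreme member and at least
    one non-extreme member, so the better-set probability is the
    closed-form complement of two hypergeometric tail terms (see
    :func:`planted_better_probability`).
    """
    rng = np.random.default_rng(seed)
    n_low = (n_library - n_high) // 2
    n_mid = n_library - n_high - n_low
    values = np.concatenate(
        [np.zeros(n_low), np.ones(n_mid), np.full(n_high, 10.0)]
    )
    rng.shuffle(values)
    certs = [f"syn-{i:04d}" for i in range(n_library)]
    table = pd.DataFrame(
        {
            "certificate": certs,
            "logp": values,
            "vdw_volume": np.full(n_library, 100.0),
            "pka": np.full(n_library, 7.0),
        }
    )
    zeros = [c for c, v in zip(certs, values) if v == 0][: set_size // 2]
    ones = [c for c, v in zip(certs, values) if v == 1][: set_size - set_size // 2]
    reference = zeros + ones
    return {
        "table": table,
        "reference": reference,
        "n_library": n_library,
        "n_high": n_high,
        "set_size": set_size,
        "expected_better": planted_better_probability(n_library, n_high, set_size),
    }


def planted_better_probability(n_library: int, n_high: int, set_size: int) -> float:
    """P(random set contains >=1 extreme and >=1 ordinary member)."""

    def c(n, k):
        return math.comb(n, k) if 0 <= k <= n else 0

    total = math.comb(n_library, set_size)
    none_high = c(n_library - n_high, set_size)
    all_high = c(n_high, set_size)
    return 1.0 - (none_high + all_high) / total


def fixture_generator(seed: int, profile: str):
    """Deterministic small inputs for a named profile."""
    builders = {
        "tiny-formulae": _tiny_formulae,
        "toy-amino-acids": _toy_amino_acids,
        "toy-nucleosides": _toy_nucleosides,
        "adaptive-synthetic": _adaptive_synthetic,
    }
    if profile not in builders:
        raise ValueError(f"unknown fixture profile {profile!r}; know {PROFILES}")
    return builders[profile](seed)
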