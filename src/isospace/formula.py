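"""Exact and fuzzy molecular formulae.

A *fuzzy formula* such as ``C2-6H0-13N1O2-4`` gives a per-element count
range and denotes the family of exact formulae in the Cartesian product
of those ranges; expanding one fuzzy formula therefore drives many
enumeration runs in a single call.  Hydrogen may be omitted entirely, in
which case every hydrogen count compatible with the heavy-atom valences
(even parity, non-negative unsaturation, connectable) is filled in.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterator, List, Tuple, Union

from .chemgraph import VALENCES, valence

__all__ = [
    "Formula",
    "FuzzyFormula",
    "parse_formula",
    "format_formula",
    "dbe",
    "is_graphical",
    "expand_fuzzy",
    "expansion_tsv",
    "ExpansionCapExceeded",
]

#: Hill-ish element output order; the placeholder B is written last,
#: matching the conventional nucleoside-formula spelling C5H9O4B.
_ELEMENT_ORDER = ["C", "H", "N", "O", "S", "B"]


class ExpansionCapExceeded(ValueError):
    """Fuzzy expansion would exceed the configured cap."""


@dataclass(frozen=True)
class Formula:
    """Exact element -> count map (counts > 0 only)."""

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Dict[str, int] | Tuple[Tuple[str, int], ...]):
        items = dict(counts)
        for el, c in items.items():
            if el not in VALENCES:
                raise ValueError(f"unknown element {el!r}")
            if c < 0:
                raise ValueError(f"negative count for {el}")
        clean = tuple(sorted((el, c) for el, c in items.items() if c > 0))
        if not any(el != "H" for el, _ in clean):
            raise ValueError("formula needs at least one non-hydrogen atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    @property
    def n_heavy(self) -> int:
        return sum(c for el, c in self.counts if el != "H")

    def heavy_atoms(self) -> List[str]:
        """Heavy-atom element list sorted by decreasing valence (ties
        alphabetical) — the fixed atom-block order used in generation."""
        out: List[str] = []
        for el, c in self.counts:
            if el != "H":
                out.extend([el] * c)
        out.sort(key=lambda e: (-valence(e), e))
        return out

    def __str__(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class FuzzyFormula:
    """Element -> (min, max) count range; H may be absent (= free)."""

    ranges: Tuple[Tuple[str, Tuple[int, int]], ...]

    def __init__(self, ranges: Dict[str, Tuple[int, int]]):
        items = {}
        for el, (lo, hi) in dict(ranges).items():
            if el not in VALENCES:
                raise ValueError(f"unknown element {el!r}")
            if not 0 <= lo <= hi:
                raise ValueError(f"malformed range {lo}-{hi} for {el}")
            items[el] = (int(lo), int(hi))
        object.__setattr__(self, "ranges", tuple(sorted(items.items())))

    def as_dict(self) -> Dict[str, Tuple[int, int]]:
        return dict(self.ranges)

    @property
    def hydrogen_free(self) -> bool:
        return "H" not in dict(self.ranges)

    def __str__(self) -> str:
        parts = []
        d = self.as_dict()
        for el in _ELEMENT_ORDER:
            if el not in d:
                continue
            lo, hi = d[el]
            parts.append(f"{el}{lo}" if lo == hi else f"{el}{lo}-{hi}")
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+)?(?:-(\d+))?")


def parse_formula(text: str) -> Union[Formula, FuzzyFormula]:
    """Parse ``C5H9O4B`` (exact) or ``C2-6H0-13N1O2-4`` (fuzzy).

    A formula is fuzzy iff at least one element carries a range.  The
    placeholder element is written ``B``.
    """
    text = text.strip()
    pos = 0
    exact: Dict[str, int] = {}
    fuzzy: Dict[str, Tuple[int, int]] = {}
    any_range = False
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(0):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, lo_s, hi_s = m.group(1), m.group(2), m.group(3)
        if el not in VALENCES:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        if el in exact or el in fuzzy:
            raise ValueError(f"element {el} repeated in formula {text!r}")
        lo = int(lo_s) if lo_s is not None else 1
        if hi_s is not None:
            hi = int(hi_s)
            if hi < lo:
                raise ValueError(f"empty range {lo}-{hi} for {el} in {text!r}")
            fuzzy[el] = (lo, hi)
            any_range = True
        else:
            exact[el] = lo
            fuzzy[el] = (lo, lo)
        pos = m.end()
    if any_range:
        return FuzzyFormula(fuzzy)
    return Formula(exact)


def format_formula(f: Formula) -> str:
    parts = []
    d = f.as_dict()
    for el in _ELEMENT_ORDER:
        if el in d:
            parts.append(el if d[el] == 1 else f"{el}{d[el]}")
    return "".join(parts)


def dbe(f: Formula) -> Fraction:
    """Degree of unsaturation: 1 + Σ n_e (v_e - 2) / 2."""
    total = Fraction(0)
    for el, c in f.counts:
        total += Fraction(c * (valence(el) - 2), 2)
    return 1 + total


def is_graphical(f: Formula) -> bool:
    """Can a connected molecule with these exact counts exist?

    Requires an even valence sum, a non-negative integer ring/double-bond
    count, enough bonding capacity to span all heavy atoms, and — when
    there is more than one heavy atom — no leftover free valence that
    only hydrogens could never absorb (each heavy atom must reach at
    least one heavy neighbor).
    """
    vsum = sum(c * valence(el) for el, c in f.counts)
    if vsum % 2:
        return False
    d = dbe(f)
    if d < 0 or d.denominator != 1:
        return False
    n_heavy = f.n_heavy
    n_h = f["H"]
    heavy_vsum = vsum - n_h
    if n_heavy == 0:
        return False
    if n_heavy == 1:
        return d == 0
    # Total heavy-heavy bond order = (heavy_vsum - n_h)/2 must connect
    # all heavy atoms: at least n_heavy - 1 bonds.
    bond_budget = heavy_vsum - n_h
    if bond_budget < 0 or bond_budget % 2:
        return False
    if bond_budget // 2 < n_heavy - 1:
        return False
    if n_heavy == 2:
        # The single bond must carry the whole budget: order <= 3 and
        # within both atoms' valences.
        heavy_vals = sorted(
            valence(el) for el, c in f.counts if el != "H" for _ in range(c)
        )
        return 1 <= bond_budget // 2 <= min(3, heavy_vals[0])
    # Univalent heavy atoms (the placeholder) consume one bond each and
    # cannot be internal: a tree needs enough >1-valent atoms.
    n_uni = sum(c for el, c in f.counts if el != "H" and valence(el) == 1)
    if n_uni == n_heavy and n_heavy > 2:
        return False
    if n_uni == n_heavy == 2:
        return bond_budget // 2 == 1
    return True


def expand_fuzzy(f: FuzzyFormula, cap: int = 10_000) -> List[Formula]:
    """All graphical exact formulae in a fuzzy formula's range product.

    When hydrogen is free (absent from the fuzzy formula) every H count
    with non-negative integer unsaturation is included.  Results are in
    deterministic lexicographic order of the element-count tuples.
    Raises :class:`ExpansionCapExceeded` when the raw product exceeds
    *cap* (narrow the ranges or raise the cap).
    """
    d = f.as_dict()
    h_range = d.pop("H", None)
    elements = sorted(d)
    spans = [range(d[el][0], d[el][1] + 1) for el in elements]
    raw = 1
    for s in spans:
        raw *= len(s)
    if h_range is not None:
        raw *= h_range[1] - h_range[0] + 1
    if raw > cap:
        raise ExpansionCapExceeded(
            f"fuzzy expansion of {f} yields {raw} candidates > cap {cap}; "
            "narrow the ranges or raise the cap"
        )
    out: List[Formula] = []
    for combo in itertools.product(*spans):
        heavy = {el: c for el, c in zip(elements, combo) if c > 0}
        if not heavy:
            continue
        heavy_vsum = sum(c * valence(el) for el, c in heavy.items())
        if h_range is None:
            # Free hydrogen: all H with dbe >= 0, matching parity.
            h_hi = heavy_vsum - 2 * (sum(heavy.values()) - 1)
            h_candidates = range(heavy_vsum % 2, max(h_hi, 0) + 1, 2)
        else:
            h_candidates = range(h_range[0], h_range[1] + 1)
        for h in h_candidates:
            counts = dict(heavy)
            if h:
                counts["H"] = h
            try:
                cand = Formula(counts)
            except ValueError:
                continue
            if is_graphical(cand):
                out.append(cand)
    out.sort(key=lambda fo: fo.counts)
    return out


def expansion_tsv(formulae: List[Formula]) -> str:
    """TSV export of an expansion: formula, unsaturation, heavy atoms."""
    lines = ["formula\tdbe\tn_heavy"]
    for f in formulae:
        lines.append(f"{f}\t{dbe(f)}\t{f.n_heavy}")
    return "\n".join(lines) + "\n"
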