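"""Adaptive-alphabet analysis: range and evenness of property coverage.

The question posed: does a reference molecular alphabet (canonically
the 20 genetically coded amino acids) cover its physico-chemical
property space — hydrophobicity, size, charge — unusually well
compared with random same-size alphabets drawn from a larger library?

Coverage of one property axis is summarized by two statistics over the
set's resolved values:

* **range** — max minus min;
* **evenness** — ``1 − CV(gaps) / sqrt(k−1)`` where the gaps are the
  differences between consecutive sorted values, CV their coefficient
  of variation and ``k`` the gap count; 1 for perfectly equidistant
  values, 0 for all mass in one gap.  Affine-invariant.

A candidate set *dominates* ("is better than") the reference when its
range and evenness are at least the reference's on every axis, with
strict improvement somewhere.  ``sample_random_sets`` Monte-Carlo
counts dominating sets among uniform without-replacement draws.

Members whose value is unresolved on an axis (non-ionizable side
chains on the pKa axis) are excluded from that axis's statistics; the
resolved counts are reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AlphabetSet",
    "AdaptiveResult",
    "range_coverage",
    "evenness",
    "coverage_stats",
    "is_better",
    "sample_random_sets",
    "DEFAULT_AXES",
]

DEFAULT_AXES = ("logp", "vdw_volume", "pka")


@dataclass(frozen=True)
class AlphabetSet:
    """A molecular alphabet: certificates plus resolved property values."""

    certificates: Tuple[str, ...]
    properties: Tuple[Tuple[str, Tuple[Optional[float], ...]], ...]
    # axis name -> per-member value (None = unresolved)

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, certificates: Sequence[str], axes: Sequence[str] = DEFAULT_AXES
    ) -> "AlphabetSet":
        certs = tuple(certificates)
        if len(set(certs)) != len(certs):
            raise ValueError("alphabet members must be distinct")
        indexed = table.set_index("certificate") if "certificate" in table else table
        missing = [c for c in certs if c not in indexed.index]
        if missing:
            raise KeyError(f"certificates absent from property table: {missing[:3]}...")
        props = []
        for axis in axes:
            vals = []
            for c in certs:
                v = indexed.loc[c, axis]
                vals.append(None if pd.isna(v) else float(v))
            props.append((axis, tuple(vals)))
        return cls(certs, tuple(props))

    def values(self, axis: str) -> List[float]:
        for name, vals in self.properties:
            if name == axis:
                return [v for v in vals if v is not None]
        raise KeyError(f"axis {axis!r} not resolved on this set")

    @property
    def axes(self) -> List[str]:
        return [name for name, _ in self.properties]


def range_coverage(s: AlphabetSet, axis: str) -> float:
    """Spread (max − min) of the resolved values on *axis*."""
    vals = s.values(axis)
    if len(vals) < 2:
        raise ValueError(f"range needs >= 2 resolved values on {axis!r}")
    return max(vals) - min(vals)


def evenness(s: AlphabetSet, axis: str) -> float:
    """Gap-uniformity in [0, 1]; 1 = perfectly equidistant values."""
    vals = sorted(s.values(axis))
    if len(vals) < 3:
        raise ValueError(f"evenness needs >= 3 resolved values on {axis!r}")
    gaps = np.diff(vals)
    mean = gaps.mean()
    if mean == 0:
        return 1.0  # all values identical: zero gaps are 'even'
    cv = gaps.std() / mean  # population CV
    cv_max = math.sqrt(len(gaps) - 1)  # all spread in a single gap
    return float(np.clip(1.0 - cv / cv_max, 0.0, 1.0))


def coverage_stats(s: AlphabetSet, axes: Sequence[str] = DEFAULT_AXES) -> Dict[str, Dict[str, float]]:
    out = {}
    for axis in axes:
        vals = s.values(axis)
        out[axis] = {
            "n_resolved": len(vals),
            "range": range_coverage(s, axis),
            "evenness": evenness(s, axis),
        }
    return out


def is_better(
    candidate: AlphabetSet, reference: AlphabetSet, axes: Sequence[str] = DEFAULT_AXES
) -> bool:
    """Strict Pareto dominance of (range, evenness) across all axes."""
    any_strict = False
    for axis in axes:
        for stat in (range_coverage, evenness):
            c, r = stat(candidate, axis), stat(reference, axis)
            if c < r:
                return False
            if c > r:
                any_strict = True
    return any_strict


@dataclass
class AdaptiveResult:
    """Monte-Carlo comparison summary."""

    n_sampled: int
    n_better: int
    seed: int
    set_size: int
    reference_stats: Dict[str, Dict[str, float]] = field(default_factory=dict)
    sample_stats_mean: Dict[str, Dict[str, float]] = field(default_factory=dict)
    better_sets: List[List[str]] = field(default_factory=list)

    @property
    def better_fraction(self) -> float:
        return self.n_better / self.n_sampled if self.n_sampled else 0.0

    def to_json(self, **extra) -> str:
        payload = {
            "n_sampled": self.n_sampled,
            "n_better": self.n_better,
            "better_fraction": self.better_fraction,
            "seed": self.seed,
            "set_size": self.set_size,
            "reference_stats": self.reference_stats,
            "sample_stats_mean": self.sample_stats_mean,
            "better_sets": self.better_sets,
        }
        payload.update(extra)
        return json.dumps(payload, indent=1, sort_keys=True)


def sample_random_sets(
    table: pd.DataFrame,
    reference: AlphabetSet,
    size: int = 20,
    n: int = 10_000,
    seed: int = 0,
    axes: Sequence[str] = DEFAULT_AXES,
    max_better_sets: int = 100,
) -> AdaptiveResult:
    """Compare *n* random same-size alphabets against *reference*.

    Draws are uniform without replacement from the property table's
    certificates.  Identical seed gives an identical result.  Better
    sets (up to *max_better_sets*) are returned as certificate lists.
    """
    indexed = table.set_index("certificate") if "certificate" in table else table
    certs = np.array(sorted(indexed.index))
    if len(certs) < size:
        raise ValueError(f"library size {len(certs)} < alphabet size {size}")
    rng = np.random.default_rng(seed)
    axis_values = {
        axis: indexed.loc[certs, axis].to_numpy(dtype=float) for axis in axes
    }
    ref_stats = coverage_stats(reference, axes)

    n_better = 0
    better_sets: List[List[str]] = []
    sums: Dict[str, Dict[str, float]] = {
        axis: {"range": 0.0, "evenness": 0.0} for axis in axes
    }
    for _ in range(n):
        idx = rng.choice(len(certs), size=size, replace=False)
        dominates = True
        any_strict = False
        cand_stats = {}
        for axis in axes:
            vals = axis_values[axis][idx]
            vals = vals[~np.isnan(vals)]
            if len(vals) < 3:
                dominates = False
                cand_stats[axis] = (0.0, 0.0)
                continue
            vals.sort()
            rng_cov = float(vals[-1] - vals[0])
            gaps = np.diff(vals)
            mean = gaps.mean()
            if mean == 0:
                ev = 1.0
            else:
                ev = float(
                    np.clip(1.0 - (gaps.std() / mean) / math.sqrt(len(gaps) - 1), 0.0, 1.0)
                )
            cand_stats[axis] = (rng_cov, ev)
            sums[axis]["range"] += rng_cov
            sums[axis]["evenness"] += ev
            if dominates:
                r_rng = ref_stats[axis]["range"]
                r_ev = ref_stats[axis]["evenness"]
                if rng_cov < r_rng or ev < r_ev:
                    dominates = False
                elif rng_cov > r_rng or ev > r_ev:
                    any_strict = True
        if dominates and any_strict:
            n_better += 1
            if len(better_sets) < max_better_sets:
                better_sets.append(sorted(certs[idx]))
    mean_stats = {
        axis: {k: v / n for k, v in d.items()} for axis, d in sums.items()
    } if n else {axis: {} for axis in axes}
    return AdaptiveResult(
        n_sampled=n,
        n_better=n_better,
        seed=seed,
        set_size=size,
        reference_stats=ref_stats,
        sample_stats_mean=mean_stats,
        better_sets=better_sets,
    )
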