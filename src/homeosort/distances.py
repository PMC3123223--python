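"""Pairwise sequence distances and difference accounting.

Kimura's two-parameter (K2P) distance corrects the observed proportions of
transitions (P) and transversions (Q) for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap, ``N`` or ``?`` are excluded pair
by pair (pairwise deletion), so each cell of a distance matrix rests on its
own effective site count.  When the log argument is non-positive the pair is
saturated and the distance is flagged undefined rather than returned as a
number.

Difference accounting counts substitutions (split into transitions and
transversions) at columns where both sequences have bases, and indel events
as maximal gap runs present in exactly one of the two sequences; a run
gapped in both contributes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import MultipleAlignment, InputError

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")

__all__ = [
    "K2PPair",
    "PairDifference",
    "DistanceMatrix",
    "k2p_distance",
    "p_distance",
    "k2p_matrix",
    "count_differences",
]


@dataclass
class K2PPair:
    distance: float  # nan when undefined
    P: float
    Q: float
    n_sites: int
    defined: bool
    saturated: bool = False


@dataclass
class PairDifference:
    substitutions: int
    transitions: int
    transversions: int
    indel_events: int
    indel_lengths: list[int]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # nan where undefined
    n_sites: np.ndarray
    defined: np.ndarray  # bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def pair(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def defined_offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.matrix[iu]
        ok = self.defined[iu]
        return vals[ok]

    @property
    def min_defined(self) -> float:
        vals = self.defined_offdiag()
        return float(vals.min()) if vals.size else math.nan

    @property
    def max_defined(self) -> float:
        vals = self.defined_offdiag()
        return float(vals.max()) if vals.size else math.nan

    def n_zero_pairs(self, tol: float = 0.0) -> int:
        return int((self.defined_offdiag() <= tol).sum())


def _comparable(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise InputError("sequences must have equal aligned length")
    aa = np.array(list(a), dtype="<U1")
    bb = np.array(list(b), dtype="<U1")
    ok = np.isin(aa, BASES) & np.isin(bb, BASES)
    return aa[ok], bb[ok]


def k2p_distance(a: str, b: str) -> K2PPair:
    """K2P distance with pairwise deletion; full precision retained
    (display rounding is the caller's concern)."""
    aa, bb = _comparable(a, b)
    n = int(aa.size)
    if n == 0:
        return K2PPair(math.nan, math.nan, math.nan, 0, defined=False)
    diff = aa != bb
    is_purine_a = np.isin(aa, ("A", "G"))
    is_purine_b = np.isin(bb, ("A", "G"))
    ts = int((diff & (is_purine_a == is_purine_b)).sum())
    tv = int((diff & (is_purine_a != is_purine_b)).sum())
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PPair(math.nan, P, Q, n, defined=False, saturated=True)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PPair(d, P, Q, n, defined=True)


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected proportion of differing comparable sites."""
    aa, bb = _comparable(a, b)
    n = int(aa.size)
    if n == 0:
        return math.nan, 0
    return float((aa != bb).mean()), n


def k2p_matrix(aln: MultipleAlignment, subset: list[str] | None = None) -> DistanceMatrix:
    ids = list(subset) if subset is not None else list(aln.ids)
    missing = [i for i in ids if i not in aln.ids]
    if missing:
        raise InputError(f"ids not in alignment: {missing}")
    k = len(ids)
    mat = np.zeros((k, k))
    nsites = np.zeros((k, k), dtype=int)
    defined = np.ones((k, k), dtype=bool)
    rows = {i: aln.row(i) for i in ids}
    for i in range(k):
        nsites[i, i] = sum(c in BASES for c in rows[ids[i]])
        for j in range(i + 1, k):
            res = k2p_distance(rows[ids[i]], rows[ids[j]])
            mat[i, j] = mat[j, i] = res.distance
            nsites[i, j] = nsites[j, i] = res.n_sites
            defined[i, j] = defined[j, i] = res.defined
    return DistanceMatrix(ids, mat, nsites, defined)


def count_differences(a: str, b: str) -> PairDifference:
    """Substitution and indel-event accounting between two aligned rows."""
    if len(a) != len(b):
        raise InputError("sequences must have equal aligned length")
    aa = np.array(list(a), dtype="<U1")
    bb = np.array(list(b), dtype="<U1")
    both = np.isin(aa, BASES) & np.isin(bb, BASES)
    diff = both & (aa != bb)
    pa = np.isin(aa, ("A", "G"))
    pb = np.isin(bb, ("A", "G"))
    ts = int((diff & (pa == pb)).sum())
    tv = int((diff & (pa != pb)).sum())
    # indel events: maximal runs gapped in exactly one of the two sequences
    lengths: list[int] = []
    state = None  # 'a' | 'b' | None
    run = 0
    for ca, cb in list(zip(a, b)) + [("$", "$")]:
        here = ("a" if (ca == "-" and cb in BASES)
                else "b" if (cb == "-" and ca in BASES) else None)
        if here == state and here is not None:
            run += 1
        else:
            if state is not None:
                lengths.append(run)
            state, run = here, 1 if here is not None else 0
    return PairDifference(ts + tv, ts, tv, len(lengths), lengths)
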