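"""Functional assessment of coding sequences.

Three classical analyses for deciding whether amplified gene copies are
functional and how they evolve:

* **Pseudogene screen** — translate the exon concatenation with the standard
  genetic code and report internal stop codons, plus exonic gap runs whose
  length is not a multiple of 3 (frame-disrupting indels).  A sequence with
  either is a putative pseudogene.

* **Pairwise Ka/Ks** (Nei & Gojobori 1986) — synonymous and non-synonymous
  site counts per codon (averaged over the two sequences), differences
  averaged over all minimal mutational pathways between differing codons,
  and a Jukes-Cantor multiple-hit correction of pS and pN.  Ka/Ks > 1
  indicates positive selection, < 1 purifying selection.

* **Tajima's relative rate test** — for two ingroup sequences and an
  outgroup, count sites where each ingroup sequence alone carries a unique
  base (the other two agreeing); under rate equality the two counts m1, m2
  have equal expectation and (m1-m2)^2/(m1+m2) is chi-square with 1 df.
  Sites with any gap/missing cell among the three are dropped (complete
  deletion over the triple).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from Bio.Data import CodonTable

from .alignment_io import (MultipleAlignment, RegionMap, InputError,
                           coding_columns)

BASES = ("A", "C", "G", "T")

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_table.stop_codons)

__all__ = [
    "PseudogeneScreen",
    "KaKsResult",
    "RateTestResult",
    "pseudogene_screen",
    "ka_ks_pairwise",
    "tajima_rrt",
    "rrt_scan",
]


@dataclass
class PseudogeneScreen:
    sequence_id: str
    internal_stops: list[tuple[int, str]]  # (codon index 1-based, region name)
    frameshift_indels: list[tuple[str, int]]  # (region name, gap-run length)
    frame_anomaly: bool
    verdict: str  # "putatively functional" | "putative pseudogene"


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float  # nan when Ks == 0 or either rate undefined
    classification: str  # positive | purifying | neutral-ish | undefined
    n_codons: int
    sites_syn: float
    sites_nonsyn: float
    diffs_syn: float
    diffs_nonsyn: float


@dataclass
class RateTestResult:
    m1: int
    m2: int
    chi2: float
    p_value: float
    significant: bool
    computable: bool
    n_sites: int
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Pseudogene screen
# ---------------------------------------------------------------------------

def pseudogene_screen(aln: MultipleAlignment, rm: RegionMap,
                      sequence_id: str) -> PseudogeneScreen:
    """Stop-codon and frame-disruption screen for one aligned sequence."""
    row = aln.row(sequence_id)
    cols = coding_columns(rm)  # 0-based, frame offset applied
    coding = [row[c] for c in cols]
    frame_anomaly = len(coding) % 3 != 0
    stops: list[tuple[int, str]] = []
    n_codons = len(coding) // 3
    for ci in range(n_codons):
        codon = "".join(coding[3 * ci:3 * ci + 3])
        if any(c not in BASES for c in codon):
            continue  # untranslatable codon (gap or ambiguity)
        if codon in STOP_CODONS and ci < n_codons - 1:
            region = rm.region_of(cols[3 * ci] + 1)
            stops.append((ci + 1, region.name if region else "?"))
    indels: list[tuple[str, int]] = []
    for r in rm.exons():
        seg = row[r.start - 1:r.end]
        run = 0
        for c in seg + "$":
            if c == "-":
                run += 1
            else:
                if run and run % 3 != 0:
                    indels.append((r.name, run))
                run = 0
    verdict = ("putative pseudogene" if (stops or indels)
               else "putatively functional")
    return PseudogeneScreen(sequence_id, stops, indels, frame_anomaly, verdict)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pairwise Ka/Ks
# ---------------------------------------------------------------------------

def _syn_sites(codon: str) -> float:
    """Fraction-weighted synonymous site count of one codon (0..3).

    A change producing a stop codon is counted as non-synonymous.
    """
    if codon in STOP_CODONS or any(c not in BASES for c in codon):
        return math.nan
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons, averaged
    over all minimal pathways; pathways through stop codons are excluded
    unless every pathway is blocked."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if CODON_TO_AA.get(nxt, "*") == CODON_TO_AA.get(cur, "*") and \
               nxt not in STOP_CODONS and cur not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    """Jukes-Cantor correction of a proportion of differences."""
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ka_ks_pairwise(a_coding: str, b_coding: str) -> KaKsResult:
    """NG86 Ka/Ks between two in-frame, equal-length coding sequences.

    Codons containing gaps, ambiguity or a stop in either sequence are
    skipped pairwise.
    """
    if len(a_coding) != len(b_coding):
        raise InputError("coding sequences must have equal length")
    if len(a_coding) % 3 != 0:
        raise InputError("coding length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a_coding), 3):
        c1, c2 = a_coding[i:i + 3].upper(), b_coding[i:i + 3].upper()
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        if math.isnan(s1) or math.isnan(s2):
            continue
        n_codons += 1
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0 or S == 0.0 or N == 0.0:
        return KaKsResult(math.nan, math.nan, math.nan, "undefined",
                          n_codons, S, N, Sd, Nd)
    ks = _jc(Sd / S)
    ka = _jc(Nd / N)
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = math.nan
        classification = "undefined"
    else:
        ratio = ka / ks
        classification = ("positive" if ratio > 1.0
                          else "purifying" if ratio < 1.0 else "neutral-ish")
    return KaKsResult(ka, ks, ratio, classification, n_codons, S, N, Sd, Nd)


# ---------------------------------------------------------------------------
# Tajima's relative rate test
# ---------------------------------------------------------------------------

def tajima_rrt(a: str, b: str, outgroup: str, alpha: float = 0.05) -> RateTestResult:
    """Chi-square relative rate test of two sequences against an outgroup."""
    if not (len(a) == len(b) == len(outgroup)):
        raise InputError("the three sequences must have equal aligned length")
    aa = np.array(list(a.upper()), dtype="<U1")
    bb = np.array(list(b.upper()), dtype="<U1")
    oo = np.array(list(outgroup.upper()), dtype="<U1")
    ok = (np.isin(aa, BASES) & np.isin(bb, BASES) & np.isin(oo, BASES))
    aa, bb, oo = aa[ok], bb[ok], oo[ok]
    m1 = int(((aa != bb) & (bb == oo)).sum())
    m2 = int(((bb != aa) & (aa == oo)).sum())
    n = int(ok.sum())
    if m1 + m2 == 0:
        return RateTestResult(m1, m2, 0.0, math.nan, False, False, n, alpha)
    stat = (m1 - m2) ** 2 / (m1 + m2)
    p = float(chi2.sf(stat, df=1))
    return RateTestResult(m1, m2, stat, p, p < alpha, True, n, alpha)


def rrt_scan(aln: MultipleAlignment, ids: list[str], outgroup_id: str,
             rm: RegionMap | None = None, alpha: float = 0.05
             ) -> tuple[pd.DataFrame, dict[str, int]]:
    """All unordered ingroup pairs tested against a fixed outgroup.

    With a region map the test runs on exon (coding) sites only.
    """
    if len(ids) < 2:
        raise InputError("need at least 2 ingroup ids")
    if rm is not None:
        cols = coding_columns(rm)
        seq = {i: "".join(aln.row(i)[c] for c in cols)
               for i in [*ids, outgroup_id]}
    else:
        seq = {i: aln.row(i) for i in [*ids, outgroup_id]}
    og = seq[outgroup_id]
    rows = []
    summary = {"n_significant": 0, "n_nonsignificant": 0, "n_uncomputable": 0}
    for x, y in itertools.combinations(ids, 2):
        res = tajima_rrt(seq[x], seq[y], og, alpha=alpha)
        rows.append({"id1": x, "id2": y, "m1": res.m1, "m2": res.m2,
                     "chi2": res.chi2, "p_value": res.p_value,
                     "significant": res.significant,
                     "computable": res.computable, "n_sites": res.n_sites})
        if not res.computable:
            summary["n_uncomputable"] += 1
        elif res.significant:
            summary["n_significant"] += 1
        else:
            summary["n_nonsignificant"] += 1
    return pd.DataFrame(rows), summary
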