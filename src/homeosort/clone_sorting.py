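"""Sorting cloned amplicon sequences into homoeolog groups.

In an allopolyploid, PCR + cloning of a single-copy nuclear locus yields a
mixture of homoeologous gene variants, contaminated by two artefact classes:

* per-clone *singletons* — polymerase/sequencing errors appearing as a rare
  base carried by exactly one clone at a column;
* *recombinant* (chimeric) clones — PCR template switching that splices the
  5' part of one variant onto the 3' part of another.

The procedure implemented here is deterministic: mask singletons, group
clones by sequence identity after masking, flag mosaic clones by runs of
group-diagnostic sites, exclude them, and pick one representative per group
(the clone with the fewest masked singletons; ties broken by smallest id).

A singleton is a base carried by exactly one clone at a column where at
least two other clones agree on some base (the rare-base-in-one-sequence
rule); the cell is masked to ``?``.  Only base-vs-base polymorphism is
masked: a private gap is real indel signal, never noise, because the error
process the masking targets is substitutional.  Masked cells act as
wildcards during grouping, and a polymerase error that collides with a
group-diagnostic site — surviving masking and leaving its clone one step
from its group — is absorbed by single-linkage merging of one-clone groups
at Hamming distance <= ``merge_threshold`` (default 1), skipped entirely
when masking found no singletons (no evidence of an error process).

Recombinant detection tests each clone against every pair of donor groups
with a single-changepoint mosaic model over the columns where the donors
differ; see :func:`detect_recombinants`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import MultipleAlignment

BASES = ("A", "C", "G", "T")

__all__ = [
    "CloneSet",
    "CloneGroup",
    "CloneGrouping",
    "RecombinantReport",
    "mask_singletons",
    "group_clones",
    "merge_singleton_groups",
    "detect_recombinants",
    "select_representative",
    "sort_clones",
    "clone_report",
]


@dataclass
class CloneSet:
    """Aligned clone library for one accession."""

    accession: str
    alignment: MultipleAlignment
    primer_tags: dict[str, str] | None = None  # clone id -> e.g. "F/K"


@dataclass
class CloneGroup:
    clone_ids: list[str]  # sorted
    consensus: str  # the shared (or dominant) masked sequence

    @property
    def size(self) -> int:
        return len(self.clone_ids)


@dataclass
class RecombinantReport:
    clone_id: str
    # ordered (donor group index, first diagnostic col, last diagnostic col);
    # columns are 1-based
    segments: list[tuple[int, int, int]]
    breakpoints: list[int]  # 1-based, midway between flanking sites


@dataclass
class CloneGrouping:
    accession: str
    groups: list[CloneGroup]
    singleton_positions: dict[str, list[int]]  # clone -> 1-based columns
    recombinants: list[RecombinantReport]
    representatives: dict[int, str]  # group index -> clone id
    n_clones: int = 0

    @property
    def recombinant_ids(self) -> set[str]:
        return {r.clone_id for r in self.recombinants}


# ---------------------------------------------------------------------------

def mask_singletons(aln: MultipleAlignment) -> tuple[MultipleAlignment, dict[str, list[int]]]:
    """Replace every rare base carried by exactly one clone with the
    column's majority base.

    A cell qualifies when its base occurs in exactly one clone at that
    column while some other base is carried by at least two clones.  The
    cell is replaced by ``?`` (unknown): replacing with the column majority
    would imprint another homoeolog's base onto the clone whenever the
    column is polymorphic between groups.  Returns the masked alignment and
    the 1-based singleton positions per clone.  With fewer than 3 clones
    the notion is undefined: a warning is issued and nothing is masked.
    """
    positions: dict[str, list[int]] = {sid: [] for sid in aln.ids}
    if aln.n_sequences < 3:
        warnings.warn("fewer than 3 clones: singleton masking skipped")
        return aln, positions
    arr = aln.array.copy()
    for j in range(aln.length):
        col = arr[:, j]
        base_mask = np.isin(col, BASES)
        obs = col[base_mask]
        vals, counts = np.unique(obs, return_counts=True)
        if len(vals) < 2 or counts.max() < 2:
            continue
        for minority in vals[counts == 1]:
            (row_idx,) = np.where(base_mask & (col == minority))
            sid = aln.ids[int(row_idx[0])]
            positions[sid].append(j + 1)
            arr[row_idx[0], j] = "?"
    masked = MultipleAlignment(list(aln.ids), ["".join(r) for r in arr])
    return masked, positions


def group_clones(masked: MultipleAlignment) -> list[CloneGroup]:
    """Partition clones identical after masking; largest groups first,
    ties by smallest member id.

    Masked (``?``) cells act as wildcards: a row containing ``?`` joins the
    group whose consensus matches it at every unmasked position (the
    largest such group when several are compatible); incompatible rows form
    their own groups, themselves bucketed by identity.
    """
    clean: dict[str, list[str]] = {}
    deferred: list[tuple[str, str]] = []
    for sid, row in zip(masked.ids, masked.rows):
        if "?" in row:
            deferred.append((sid, row))
        else:
            clean.setdefault(row, []).append(sid)
    groups = [CloneGroup(sorted(ids), seq) for seq, ids in clean.items()]
    groups.sort(key=lambda g: (-g.size, g.clone_ids[0]))
    # rows with masked cells join the largest clean group they are
    # compatible with, then cluster among themselves (wildcard identity),
    # filling unknown cells from cluster mates
    deferred.sort(key=lambda it: (it[1].count("?"), it[0]))
    clusters: list[tuple[list[str], list[str]]] = []  # (consensus chars, ids)
    for sid, row in deferred:
        compatible = [g for g in groups
                      if all(a == "?" or a == b
                             for a, b in zip(row, g.consensus))]
        if compatible:
            compatible[0].clone_ids = sorted(compatible[0].clone_ids + [sid])
            continue
        for cons, ids in clusters:
            if all(a == "?" or c == "?" or a == c
                   for a, c in zip(row, cons)):
                for k, a in enumerate(row):
                    if cons[k] == "?" and a != "?":
                        cons[k] = a
                ids.append(sid)
                break
        else:
            clusters.append((list(row), [sid]))
    groups += [CloneGroup(sorted(ids), "".join(cons))
               for cons, ids in clusters]
    groups.sort(key=lambda g: (-g.size, g.clone_ids[0]))
    return groups


def _hamming(a: str, b: str) -> int:
    """Differences between two rows; masked ``?`` cells do not count."""
    return sum(1 for x, y in zip(a, b) if x != y and x != "?" and y != "?")


def merge_singleton_groups(groups: list[CloneGroup],
                           threshold: int = 1) -> list[CloneGroup]:
    """Single-linkage absorption of one-clone groups into a multi-clone
    group whose consensus lies within ``threshold`` differences (unique
    nearest target only; ties leave the group alone)."""
    big = [g for g in groups if g.size >= 2]
    if not big:
        return groups
    merged: list[CloneGroup] = [CloneGroup(list(g.clone_ids), g.consensus)
                                for g in big]
    leftovers: list[CloneGroup] = []
    for g in groups:
        if g.size >= 2:
            continue
        dists = [_hamming(g.consensus, t.consensus) for t in merged]
        order = sorted(range(len(merged)), key=lambda i: dists[i])
        if dists[order[0]] <= threshold and (
                len(order) == 1 or dists[order[1]] > dists[order[0]]):
            target = merged[order[0]]
            target.clone_ids = sorted(target.clone_ids + g.clone_ids)
        else:
            leftovers.append(g)
    out = merged + leftovers
    out.sort(key=lambda g: (-g.size, g.clone_ids[0]))
    return out


def pair_diagnostic_units(cons_a: np.ndarray, cons_b: np.ndarray) -> list[np.ndarray]:
    """0-based column groups where two consensus rows differ; adjacent
    differing columns involving a gap in either row collapse into one unit
    (an indel is a single event, not one difference per column)."""
    cols = np.where(cons_a != cons_b)[0]
    units: list[list[int]] = []
    for c in cols:
        gappy = cons_a[c] == "-" or cons_b[c] == "-"
        if (units and c == units[-1][-1] + 1 and gappy
                and (cons_a[units[-1][-1]] == "-"
                     or cons_b[units[-1][-1]] == "-")):
            units[-1].append(c)
        else:
            units.append([c])
    return [np.array(u) for u in units]


def detect_recombinants(
    masked: MultipleAlignment,
    groups: list[CloneGroup],
    min_run: int = 3,
    min_group_size: int = 2,
    max_mismatch: int = 3,
) -> list[RecombinantReport]:
    """Flag clones that are single-switch mosaics of two donor groups.

    For every pair of donor groups (size >= ``min_group_size``), the columns
    where the two donor consensus sequences differ are diagnostic; adjacent
    diagnostic columns inside a shared gap run collapse into one *unit* (an
    indel is one event).  A clone is recombinant for a pair when some single
    changepoint splits the units so that the clone matches donor A on one
    side (>= ``min_run`` units) and donor B on the other (>= ``min_run``
    units), and the stitched two-donor model reproduces the clone's whole
    sequence up to ``max_mismatch`` columns.  The whole-sequence fit is what
    separates a true template switch — which matches its two donors almost
    everywhere — from a clone of a third, phylogenetically intermediate
    lineage, which matches the donor pair only in an interleaved pattern at
    their mutual differences while deviating elsewhere.  A chimera with
    fewer than ``min_run`` diagnostic units on one side of its breakpoint
    is a documented false negative.
    """
    donors = [(gi, g) for gi, g in enumerate(groups) if g.size >= min_group_size]
    if len(donors) < 2:
        return []
    arr = masked.array
    cons = {gi: np.array(list(g.consensus), dtype="<U1") for gi, g in donors}
    pair_units = {
        (gi, gj): pair_diagnostic_units(cons[gi], cons[gj])
        for (gi, _), (gj, _) in itertools.combinations(donors, 2)
    }
    member_of: dict[str, int] = {}
    for gi, g in donors:
        for cid in g.clone_ids:
            member_of[cid] = gi
    replicated: set[str] = set()
    for g in groups:
        if g.size >= 3:
            replicated.update(g.clone_ids)
    reports: list[RecombinantReport] = []
    for r, sid in enumerate(masked.ids):
        if sid in replicated:
            # three or more identical molecules essentially never share an
            # independent PCR template-switch event: treat as genuine
            continue
        best: RecombinantReport | None = None
        best_score = math.inf
        for (gi, gj), units in pair_units.items():
            if member_of.get(sid) in (gi, gj):
                continue  # a clone trivially "fits" a pair containing its own group
            m = len(units)
            if m < 2 * min_run:
                continue
            match_i = np.array([(arr[r, u] == cons[gi][u]).all()
                                for u in units], dtype=int)
            match_j = np.array([(arr[r, u] == cons[gj][u]).all()
                                for u in units], dtype=int)
            diff_i = arr[r] != cons[gi]
            diff_j = arr[r] != cons[gj]
            cum_i = np.concatenate([[0], np.cumsum(diff_i)])
            cum_j = np.concatenate([[0], np.cumsum(diff_j)])
            ci = np.concatenate([[0], np.cumsum(match_i)])
            cj = np.concatenate([[0], np.cumsum(match_j)])
            for first, second in ((gi, gj), (gj, gi)):
                cf, cs_ = (ci, cj) if first == gi else (cj, ci)
                mf, ms = (match_i, match_j) if first == gi else (match_j, match_i)
                df, ds = (cum_i, cum_j) if first == gi else (cum_j, cum_i)
                for k in range(min_run, m - min_run + 1):
                    pre, suf = int(cf[k]), int(cs_[-1] - cs_[k])
                    if pre < min_run or suf < min_run:
                        continue
                    # switch column: midway between unit k-1 and unit k
                    cut = (int(units[k - 1][-1]) + int(units[k][0])) // 2 + 1
                    mism = int(df[cut] + (ds[-1] - ds[cut]))
                    if mism > max_mismatch:
                        continue
                    if mism < best_score:
                        left = [units[i] for i in range(k) if mf[i]]
                        right = [units[i] for i in range(k, m) if ms[i]]
                        segments = [
                            (first, int(left[0][0]) + 1, int(left[-1][-1]) + 1),
                            (second, int(right[0][0]) + 1,
                             int(right[-1][-1]) + 1)]
                        best = RecombinantReport(sid, segments, [cut])
                        best_score = mism
        if best is not None:
            reports.append(best)
    return reports


def select_representative(group: CloneGroup,
                          singleton_counts: dict[str, int]) -> str:
    """Clone with the fewest singletons; ties broken by lexicographically
    smallest id."""
    return min(group.clone_ids,
               key=lambda cid: (singleton_counts.get(cid, 0), cid))


def sort_clones(cs: CloneSet, min_run: int = 3, min_group_size: int = 2,
                merge_threshold: int = 1) -> CloneGrouping:
    """Full procedure: mask singletons -> group -> absorb one-clone error
    groups -> flag recombinants -> exclude them -> choose representatives.

    Representative cost per clone = masked singletons + residual distance
    to its group consensus, so an error-free clone wins whenever one exists.
    """
    masked, positions = mask_singletons(cs.alignment)
    groups = group_clones(masked)
    any_singletons = any(positions.values())
    if any_singletons and merge_threshold > 0:
        groups = merge_singleton_groups(groups, threshold=merge_threshold)
    reports = detect_recombinants(masked, groups, min_run=min_run,
                                  min_group_size=min_group_size)
    bad = {r.clone_id for r in reports}
    clean_groups = []
    for g in groups:
        keep = [cid for cid in g.clone_ids if cid not in bad]
        if keep:
            clean_groups.append(CloneGroup(keep, g.consensus))
    clean_groups.sort(key=lambda g: (-g.size, g.clone_ids[0]))
    row_of = dict(zip(masked.ids, masked.rows))
    reps = {}
    for gi, g in enumerate(clean_groups):
        costs = {cid: len(positions.get(cid, ()))
                 + _hamming(row_of[cid], g.consensus)
                 for cid in g.clone_ids}
        reps[gi] = select_representative(g, costs)
    return CloneGrouping(
        accession=cs.accession,
        groups=clean_groups,
        singleton_positions=positions,
        recombinants=reports,
        representatives=reps,
        n_clones=cs.alignment.n_sequences,
    )


def clone_report(grouping: CloneGrouping) -> pd.DataFrame:
    """Per-accession summary table: total clones / recombinants, group sizes
    and representatives (the "clones sequenced / recombinants" layout of
    clone-library studies)."""
    n_rec = len(grouping.recombinants)
    rows = []
    for gi, g in enumerate(grouping.groups):
        rows.append({
            "accession": grouping.accession,
            "clones_recombinants": f"{grouping.n_clones}/{n_rec}",
            "group": gi + 1,
            "size": g.size,
            "representative": grouping.representatives[gi],
            "rep_singletons": len(
                grouping.singleton_positions.get(grouping.representatives[gi], [])),
        })
    return pd.DataFrame(rows)
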