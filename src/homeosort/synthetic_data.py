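"""Synthetic allopolyploid amplicon clone libraries with known ground truth.

The generator emulates what a cloning experiment on a single-copy nuclear
locus of an allopolyploid produces:

1. **Progenitor panel** — homoeolog haplotypes evolved along a tree under a
   Kimura two-parameter substitution process (transition/transversion rate
   ratio ``kappa``), with intron-only deletions and in-frame exons; one
   lineage can be pseudogenized (premature stop plus a frame-breaking
   10-bp exon deletion).
2. **Clone library** — each clone copies one homoeolog (multinomial over
   configured proportions), or with probability ``chimera_fraction`` splices
   two donors at a uniform random breakpoint (PCR template switching), then
   receives independent per-site polymerase errors.

Default study conditions: 4 progenitor lineages, tree depth 0.02
substitutions/site (within-library divergences of roughly 0.01-0.04, the
range observed between homoeolog variants of one accession), 30 clones per
accession, per-site error rate 1e-3 and a 15% chimera fraction; the
reference-study emulation (:func:`study_panel_config`) raises the chimera
fraction to the ~19% of the emulated experiment.

Every artefact is recorded in :class:`SimTruth`, so recovery of groups,
chimeras and representatives can be scored exactly.

Defaults mirror a typical clone-library study design on hexaploid
wheatgrass: 26-40 clones per accession, roughly 19% chimeric clones,
progenitor divergences spanning K2P ~ 0.003-0.07, a 718-column locus of
three exon and two intron blocks, and a pseudogenized lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import MultipleAlignment, Region, RegionMap
from .clone_sorting import CloneSet

BASES = np.array(["A", "C", "G", "T"])
_IDX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_STOPS = {"TAA", "TAG", "TGA"}

__all__ = [
    "SimConfig",
    "SimTruth",
    "CloneRecord",
    "default_region_map",
    "simulate_progenitors",
    "simulate_clone_library",
    "recovery_harness",
    "study_panel_config",
    "STUDY_ACCESSIONS",
]


def default_region_map(length: int = 718) -> RegionMap:
    """GBSSI-style exon/intron template: partial exon, intron, exon,
    intron, partial exon; reading frame starts at the second exon column."""
    if length == 718:
        regions = [
            Region("exon9", 1, 81, "exon"),
            Region("intron9", 82, 189, "intron"),
            Region("exon10", 190, 369, "exon"),
            Region("intron10", 370, 582, "intron"),
            Region("exon11", 583, 718, "exon"),
        ]
        return RegionMap(regions, frame_offset=1)
    # generic template with the same proportions
    e = length // 5
    regions = [
        Region("exon1", 1, e, "exon"),
        Region("intron1", e + 1, 2 * e, "intron"),
        Region("exon2", 2 * e + 1, 3 * e, "exon"),
        Region("intron2", 3 * e + 1, 4 * e, "intron"),
        Region("exon3", 4 * e + 1, length, "exon"),
    ]
    total = e + e + (length - 4 * e)
    return RegionMap(regions, frame_offset=total % 3)


@dataclass
class SimConfig:
    """Study-design parameters of a simulated clone experiment."""

    n_progenitors: int = 4
    tree: str | None = None  # newick with branch lengths; None -> random
    depth: float = 0.02  # expected substitutions/site root-to-tip (random tree)
    length: int = 718
    kappa: float = 2.0  # transition/transversion rate ratio
    indel_rate: float = 0.15  # expected intron deletions per lineage
    indel_lengths: tuple[int, ...] = (2, 3, 4, 5, 6, 8, 10)
    clones_per_accession: int = 30
    proportions: tuple[float, ...] | None = None  # per-lineage; None -> uniform
    error_rate: float = 1e-3  # per clone-site substitution probability
    chimera_fraction: float = 0.15
    pseudogene_lineage: str | None = None  # e.g. "P4"
    pseudogene_deletion: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progenitors < 2:
            raise ValueError("need at least 2 progenitor lineages")
        for r in (self.error_rate, self.chimera_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class CloneRecord:
    clone_id: str
    source: str  # lineage of origin (first donor for chimeras)
    is_chimera: bool
    donors: tuple[str, str] | None
    breakpoint: int | None  # 1-based column of the first base from donor 2
    error_positions: list[int]  # 1-based columns


@dataclass
class SimTruth:
    tree_newick: str
    clones: dict[str, CloneRecord] = field(default_factory=dict)
    pseudogene_lineages: list[str] = field(default_factory=list)

    def lineage_of(self, clone_id: str) -> str:
        return self.clones[clone_id].source

    def chimera_ids(self) -> set[str]:
        return {c.clone_id for c in self.clones.values() if c.is_chimera}


# ---------------------------------------------------------------------------
# Substitution process
# ---------------------------------------------------------------------------

def _k2p_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after branch length t
    (expected substitutions/site), under K2P with ts/tv rate ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta * t) \
        - 0.5 * math.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * math.exp(-4.0 * beta * t)
    return p_ts, p_tv


def _evolve(seq_idx: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = _k2p_probs(t, kappa)
    u = rng.random(seq_idx.size)
    out = seq_idx.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = _TRANSITION[seq_idx[ts_mask]]
    out[tv1_mask] = _TRANSVERSIONS[seq_idx[tv1_mask], 0]
    out[tv2_mask] = _TRANSVERSIONS[seq_idx[tv2_mask], 1]
    return out


def _fix_exon_stops(child: np.ndarray, parent: np.ndarray,
                    coding_cols: list[int]) -> None:
    """Revert codons that mutated into internal stops (selection against
    nonsense changes keeps functional copies translatable)."""
    n_codons = len(coding_cols) // 3
    for ci in range(n_codons - 1):  # final codon may legitimately be a stop
        cols = coding_cols[3 * ci:3 * ci + 3]
        codon = "".join(BASES[child[c]] for c in cols)
        if codon in _STOPS:
            for c in cols:
                child[c] = parent[c]


# ---------------------------------------------------------------------------
# Progenitor panel
# ---------------------------------------------------------------------------

def _random_tree(names: list[str], depth: float,
                 rng: np.random.Generator) -> "_SimNode":
    nodes = [_SimNode(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = _SimNode(children=[a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    _assign_depths(root, depth, rng)
    return root


@dataclass
class _SimNode:
    name: str | None = None
    children: list["_SimNode"] = field(default_factory=list)
    length: float = 0.0

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return (f"({inner}):{self.length:.6f}" if self.length
                else f"({inner})")


def _assign_depths(root: _SimNode, depth: float,
                   rng: np.random.Generator) -> None:
    """Give every root-to-tip path total length ``depth`` with random
    internal split points."""

    def walk(node: _SimNode, remaining: float) -> None:
        for child in node.children:
            if child.children:
                # internal edges take at most ~half the remaining height so
                # terminal branches keep within-library variants apart, as
                # observed clone-library divergences do
                frac = rng.uniform(0.2, 0.45)
                child.length = remaining * frac
                walk(child, remaining * (1.0 - frac))
            else:
                child.length = remaining

    walk(root, depth)


def _parse_sim_tree(newick: str) -> _SimNode:
    import dendropy
    dt = dendropy.Tree.get(data=newick, schema="newick")

    def conv(nd) -> _SimNode:
        out = _SimNode(name=nd.taxon.label if nd.taxon else None,
                       length=nd.edge.length or 0.0)
        out.children = [conv(c) for c in nd.child_nodes()]
        return out

    return conv(dt.seed_node)


def simulate_progenitors(cfg: SimConfig, rng: np.random.Generator | None = None
                         ) -> tuple[MultipleAlignment, str, RegionMap]:
    """Evolve a homoeolog haplotype panel; returns (panel, true newick,
    region map)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rm = default_region_map(cfg.length)
    if cfg.tree is not None:
        root = _parse_sim_tree(cfg.tree)
    else:
        names = [f"P{i + 1}" for i in range(cfg.n_progenitors)]
        root = _random_tree(names, cfg.depth, rng)

    coding_cols = []
    for r in rm.exons():
        coding_cols.extend(range(r.start - 1, r.end))
    coding_cols = coding_cols[rm.frame_offset:]

    # root sequence: uniform introns, stop-free exon codons
    seq = rng.integers(0, 4, size=cfg.length)
    n_codons = len(coding_cols) // 3
    for ci in range(n_codons):
        cols = coding_cols[3 * ci:3 * ci + 3]
        while "".join(BASES[seq[c]] for c in cols) in _STOPS:
            for c in cols:
                seq[c] = rng.integers(0, 4)

    leaves: dict[str, np.ndarray] = {}

    def walk(node: _SimNode, parent_seq: np.ndarray) -> None:
        child_seq = _evolve(parent_seq, node.length, cfg.kappa, rng) \
            if node.length > 0 else parent_seq.copy()
        _fix_exon_stops(child_seq, parent_seq, coding_cols)
        if not node.children:
            leaves[node.name] = child_seq
        for c in node.children:
            walk(c, child_seq)

    walk(root, seq)

    rows: dict[str, list[str]] = {n: [BASES[i] for i in s]
                                  for n, s in leaves.items()}
    # intron-only deletions, per lineage
    introns = rm.introns()
    for name in rows:
        n_dels = rng.poisson(cfg.indel_rate)
        for _ in range(n_dels):
            intron = introns[rng.integers(0, len(introns))]
            ln = int(cfg.indel_lengths[rng.integers(0, len(cfg.indel_lengths))])
            ln = min(ln, intron.span - 2)
            start = int(rng.integers(intron.start, intron.end - ln + 2))
            for c in range(start - 1, start - 1 + ln):
                rows[name][c] = "-"
    pseudo: list[str] = []
    if cfg.pseudogene_lineage is not None:
        name = cfg.pseudogene_lineage
        if name not in rows:
            raise ValueError(f"pseudogene lineage {name!r} not in panel")
        pseudo.append(name)
        _pseudogenize(rows[name], rm, cfg.pseudogene_deletion, coding_cols, rng)

    order = sorted(rows)
    panel = MultipleAlignment(order, ["".join(rows[n]) for n in order])
    panel._sim_pseudogenes = pseudo  # type: ignore[attr-defined]
    nwk = root.newick()
    if nwk.endswith(":0.000000"):
        nwk = nwk[: -len(":0.000000")]
    return panel, nwk + ";", rm


def _pseudogenize(row: list[str], rm: RegionMap, deletion: int,
                  coding_cols: list[int], rng: np.random.Generator) -> None:
    """Inject a premature stop (mid exon) and a frame-breaking deletion in
    the last exon."""
    n_codons = len(coding_cols) // 3
    ci = n_codons // 2
    cols = coding_cols[3 * ci:3 * ci + 3]
    for c, b in zip(cols, "TAA"):
        row[c] = b
    last = rm.exons()[-1]
    start = last.start + (last.span - deletion) // 2
    for c in range(start - 1, start - 1 + deletion):
        row[c] = "-"


# ---------------------------------------------------------------------------
# Clone library
# ---------------------------------------------------------------------------

def simulate_clone_library(panel: MultipleAlignment, cfg: SimConfig,
                           rng: np.random.Generator | None = None,
                           accession: str = "acc1",
                           lineages: list[str] | None = None,
                           truth: SimTruth | None = None,
                           tree_newick: str = "",
                           exact_counts: dict[str, int] | None = None,
                           n_chimeras: int | None = None,
                           ) -> tuple[CloneSet, SimTruth]:
    """Sample a clone library from a homoeolog panel.

    Each clone copies one lineage, or (with probability
    ``cfg.chimera_fraction``) splices two distinct donors at a uniform
    random column; per-site errors are applied afterwards at base
    positions only.

    ``exact_counts``/``n_chimeras`` fix the realized composition instead of
    sampling it — used when a per-accession composition table is the input.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    lineages = list(lineages) if lineages is not None else list(panel.ids)
    if exact_counts is not None:
        lineages = list(exact_counts)
    if cfg.proportions is not None:
        props = np.asarray(cfg.proportions, dtype=float)
        props = props / props.sum()
    elif exact_counts is not None:
        props = np.asarray([exact_counts[l] for l in lineages], float)
        props = props / props.sum()
    else:
        props = np.full(len(lineages), 1.0 / len(lineages))
    truth = truth if truth is not None else SimTruth(tree_newick)
    L = panel.length
    if exact_counts is not None:
        n_chim = n_chimeras or 0
        plan = [("pure", l) for l in lineages
                for _ in range(exact_counts[l])]
        plan += [("chimera", None)] * n_chim
        order = rng.permutation(len(plan))
        plan = [plan[i] for i in order]
        n_total = len(plan)
    else:
        plan = None
        n_total = cfg.clones_per_accession
    ids, rows = [], []
    for k in range(n_total):
        cid = f"{accession}_c{k + 1:03d}"
        if plan is not None:
            make_chimera = plan[k][0] == "chimera"
        else:
            make_chimera = (rng.random() < cfg.chimera_fraction
                            and len(lineages) >= 2)
        if make_chimera and len(lineages) >= 2:
            d1, d2 = rng.choice(len(lineages), size=2, replace=False, p=props)
            bp = int(rng.integers(2, L))  # first column taken from donor 2
            s1, s2 = panel.row(lineages[d1]), panel.row(lineages[d2])
            row = list(s1[:bp - 1] + s2[bp - 1:])
            rec = CloneRecord(cid, lineages[d1], True,
                              (lineages[d1], lineages[d2]), bp, [])
        else:
            if plan is not None and plan[k][1] is not None:
                src = plan[k][1]
            else:
                src = lineages[int(rng.choice(len(lineages), p=props))]
            row = list(panel.row(src))
            rec = CloneRecord(cid, src, False, None, None, [])
        # per-site PCR errors at base positions
        if cfg.error_rate > 0:
            base_pos = [i for i, c in enumerate(row) if c in "ACGT"]
            hits = np.asarray(base_pos)[rng.random(len(base_pos))
                                        < cfg.error_rate]
            for pos in hits:
                old = row[pos]
                choices = [b for b in "ACGT" if b != old]
                row[pos] = choices[int(rng.integers(0, 3))]
                rec.error_positions.append(int(pos) + 1)
        ids.append(cid)
        rows.append("".join(row))
        truth.clones[cid] = rec
    cs = CloneSet(accession, MultipleAlignment(ids, rows),
                  primer_tags={i: "F/K" for i in ids})
    return cs, truth


# ---------------------------------------------------------------------------
# End-to-end recovery harness
# ---------------------------------------------------------------------------

def recovery_harness(cfg: SimConfig, min_run: int = 3) -> dict[str, float]:
    """Simulate one accession, run the sorting pipeline, and score recovery
    against the ground truth."""
    from sklearn.metrics import adjusted_rand_score

    from .clone_sorting import sort_clones
    from .distances import k2p_matrix
    from .phylogeny import Tree, nj_tree, robinson_foulds

    rng = np.random.default_rng(cfg.seed)
    panel, newick, rm = simulate_progenitors(cfg, rng)
    cs, truth = simulate_clone_library(panel, cfg, rng, tree_newick=newick)
    grouping = sort_clones(cs, min_run=min_run)

    true_chim = truth.chimera_ids()
    flagged = grouping.recombinant_ids
    tp = len(true_chim & flagged)
    sensitivity = tp / len(true_chim) if true_chim else math.nan
    precision = tp / len(flagged) if flagged else math.nan

    # a chimera is detectable when >= min_run donor-diagnostic sites flank
    # the breakpoint on both sides
    from .clone_sorting import pair_diagnostic_units

    pure_counts: dict[str, int] = {}
    for rec in truth.clones.values():
        if not rec.is_chimera:
            pure_counts[rec.source] = pure_counts.get(rec.source, 0) + 1
    detectable = set()
    for cid in true_chim:
        rec = truth.clones[cid]
        d1, d2 = rec.donors
        if pure_counts.get(d1, 0) < 2 or pure_counts.get(d2, 0) < 2:
            continue  # donor group absent from the library: no reference
        r1 = np.array(list(panel.row(d1)), dtype="<U1")
        r2 = np.array(list(panel.row(d2)), dtype="<U1")
        units = pair_diagnostic_units(r1, r2)
        starts = np.array([u[0] + 1 for u in units])  # 1-based
        left = int((starts < rec.breakpoint).sum())
        right = int((starts >= rec.breakpoint).sum())
        if left >= min_run and right >= min_run:
            detectable.add(cid)
    sens_detectable = (len(detectable & flagged) / len(detectable)
                       if detectable else math.nan)

    # grouping accuracy over truly pure clones that were not flagged
    pure = [cid for cid in cs.alignment.ids
            if cid not in true_chim and cid not in flagged]
    label_true = [truth.lineage_of(cid) for cid in pure]
    assign = {}
    for gi, g in enumerate(grouping.groups):
        for cid in g.clone_ids:
            assign[cid] = gi
    label_pred = [assign[cid] for cid in pure]
    ari = adjusted_rand_score(label_true, label_pred) if pure else math.nan

    true_lineages = {truth.lineage_of(cid) for cid in cs.alignment.ids
                     if cid not in true_chim}
    group_count_exact = float(len(grouping.groups) == len(true_lineages))
    # lineage-group recovery: groups holding at least one truly pure clone
    # must correspond 1:1 to the lineages present; extra groups made of
    # undetected chimeras are scored through sensitivity instead
    lineage_of_group = []
    pure_groups_clean = True
    for g in grouping.groups:
        srcs = {truth.lineage_of(c) for c in g.clone_ids
                if c not in true_chim}
        if len(srcs) > 1:
            pure_groups_clean = False
        if srcs:
            lineage_of_group.append(srcs.pop() if len(srcs) == 1 else None)
    lineage_groups_exact = float(
        pure_groups_clean
        and len(lineage_of_group) == len(set(lineage_of_group))
        == len(true_lineages))

    reps = list(grouping.representatives.values())
    rep_clean = (sum(1 for r in reps
                     if not truth.clones[r].error_positions) / len(reps)
                 if reps else math.nan)

    # NJ on the representatives vs the true progenitor tree
    rf = math.nan
    rep_sources = {truth.lineage_of(r) for r in reps
                   if not truth.clones[r].is_chimera}
    if len(rep_sources) >= 4 and len(rep_sources) == len(reps):
        dm = k2p_matrix(cs.alignment, subset=reps)
        if dm.defined.all():
            nj = nj_tree(dm)
            for n, lbl in list(nj.labels.items()):
                nj.labels[n] = truth.lineage_of(lbl)
            true_tree = Tree.from_newick(newick)
            keep = {nj.labels[n] for n in nj.leaves()}
            rf = float(robinson_foulds(_restrict(true_tree, keep), nj))
    return {
        "n_groups": float(len(grouping.groups)),
        "n_true_lineages": float(len(true_lineages)),
        "group_count_exact": group_count_exact,
        "lineage_groups_exact": lineage_groups_exact,
        "ari": ari,
        "chimera_sensitivity": sensitivity,
        "chimera_sensitivity_detectable": sens_detectable,
        "n_detectable_chimeras": float(len(detectable)),
        "chimera_precision": precision,
        "representative_error_free": rep_clean,
        "nj_rf_distance": rf,
        "n_recombinant_true": float(len(true_chim)),
        "n_recombinant_flagged": float(len(flagged)),
    }


def _restrict(tree, keep: set[str]):
    """Restrict a tree to a leaf subset (prune others, suppress degree-2)."""
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in list(t.adj):
            if n in t.labels and t.labels[n] not in keep and len(t.adj[n]) <= 1:
                for nb in list(t.adj[n]):
                    t.remove_edge(n, nb)
                del t.adj[n]
                t.labels.pop(n, None)
                changed = True
            elif n not in t.labels and len(t.adj[n]) == 2:
                a, b = sorted(t.adj[n])
                t.remove_edge(n, a)
                t.remove_edge(n, b)
                t.add_edge(a, b)
                del t.adj[n]
                changed = True
            elif n not in t.labels and len(t.adj[n]) <= 1:
                for nb in list(t.adj[n]):
                    t.remove_edge(n, nb)
                del t.adj[n]
                changed = True
    return t


# ---------------------------------------------------------------------------
# Reference-study emulation
# ---------------------------------------------------------------------------

# Accession layouts of the emulated clone experiment: library size, number of
# chimeric clones, and the homoeolog lineages present with their clone counts.
STUDY_ACCESSIONS: dict[str, dict] = {
    "acc1": {"clones": 40, "recombinant": 8,
             "lineages": {"h1b": 10, "h1c3e": 19, "h1d": 3}},
    "acc2": {"clones": 26, "recombinant": 3,
             "lineages": {"h2b3b": 17, "h2c": 5, "h2d": 1}},
    "acc3": {"clones": 34, "recombinant": 10,
             "lineages": {"h2b3b": 9, "h3c": 1, "h3d": 2, "h1c3e": 11,
                          "h3f": 1}},
    "acc4": {"clones": 32, "recombinant": 4,
             "lineages": {"h4b": 20, "h4c": 2, "h4d": 6}},
}

# Progenitor haplotype tree for the emulation.  Twelve distinct ingroup
# haplotypes in four clades (Dasypyrum-, Thinopyrum-, Pseudoroegneria- and
# Aegilops-like) plus an outgroup; terminal/internal lengths are calibrated
# so pairwise K2P distances span roughly 0.003-0.07, with one accelerated
# lineage (h3f) and two haplotypes shared between accessions
# (h1c == h3e -> "h1c3e"; h2b == h3b -> "h2b3b").
STUDY_TREE = (
    "((((h1b:0.0015,h4b:0.0015):0.0125,(h2c:0.008,h2d:0.008):0.006,"
    "(h2b3b:0.009,h3c:0.009):0.005):0.008,"
    "(h1c3e:0.010,(h3d:0.004,h4d:0.004):0.006):0.012,"
    "((h3f:0.020,h4c:0.004):0.008,h1d:0.012):0.010):0.014,"
    "outgroup:0.05);"
)

# representative clone -> panel haplotype; the two shared haplotypes give
# the emulation its two identical representative pairs (1c/3e and 2b/3b)
STUDY_REPRESENTATIVES: dict[str, str] = {
    "1b": "h1b", "1c": "h1c3e", "1d": "h1d",
    "2b": "h2b3b", "2c": "h2c", "2d": "h2d",
    "3b": "h2b3b", "3c": "h3c", "3d": "h3d", "3e": "h1c3e", "3f": "h3f",
    "4b": "h4b", "4c": "h4c", "4d": "h4d",
}


def study_representative_alignment(panel: MultipleAlignment
                                   ) -> MultipleAlignment:
    """The 14 representative sequences of the emulation (plus outgroup),
    expanded from the haplotype panel."""
    ids = sorted(STUDY_REPRESENTATIVES)
    rows = [panel.row(STUDY_REPRESENTATIVES[i]) for i in ids]
    return MultipleAlignment(ids + ["outgroup"],
                             rows + [panel.row("outgroup")])


def study_panel_config(seed: int = 0) -> SimConfig:
    """Configuration of the reference-study emulation (fixed haplotype tree,
    ~19% chimeras, per-accession layouts in :data:`STUDY_ACCESSIONS`)."""
    return SimConfig(
        n_progenitors=13,
        tree=STUDY_TREE,
        length=718,
        kappa=2.0,
        indel_rate=0.8,
        indel_lengths=(4, 8),
        clones_per_accession=33,
        error_rate=1e-3,
        chimera_fraction=0.19,
        seed=seed,
    )
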