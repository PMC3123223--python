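"""Distance and parsimony tree machinery.

Trees are unrooted and binary, stored as an adjacency map over integer
nodes with leaf labels; newick I/O goes through dendropy-compatible
strings.  All tie-breaking (NJ pair choice, canonical newick ordering,
move enumeration) is lexicographic by taxon label so every routine is
deterministic given its seed.

* :func:`nj_tree` — classical neighbor joining with exact branch lengths
  (recovers any additive metric).
* :func:`parsimony_length` — Fitch counting for nucleotide and unordered
  coded characters, Sankoff dynamic programming for characters carrying a
  step-cost matrix; ``?`` (missing) never adds steps.
* :func:`mp_search` — heuristic maximum parsimony: random-addition starting
  trees followed by NNI/SPR/TBR branch swapping to a local optimum, with a
  capped buffer of equally best trees.
* :func:`ci_ri` — ensemble consistency and retention indices.
* :func:`bootstrap_consensus` — character resampling, per-replicate reduced
  search, and a majority-rule consensus at a chosen support threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import MultipleAlignment, InputError
from .distances import DistanceMatrix
from .indel_coding import CodedMatrix

__all__ = [
    "Tree",
    "SearchResult",
    "nj_tree",
    "parsimony_length",
    "per_character_steps",
    "mp_search",
    "ci_ri",
    "bootstrap_consensus",
    "robinson_foulds",
]

_DNA_BITS = {"A": 1, "C": 2, "G": 4, "T": 8,
             "N": 15, "?": 15, "-": 15}


class Tree:
    """Unrooted tree over labelled leaves (adjacency representation)."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.labels: dict[int, str] = {}
        self.lengths: dict[frozenset[int], float] = {}
        self.supports: dict[frozenset[str], float] = {}
        self._next = 0

    # -- construction -----------------------------------------------------
    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float | None = None) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        if length is not None:
            self.lengths[frozenset((u, v))] = length

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.lengths.pop(frozenset((u, v)), None)

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.labels = dict(self.labels)
        t.lengths = dict(self.lengths)
        t.supports = dict(self.supports)
        t._next = self._next
        return t

    # -- queries ----------------------------------------------------------
    def leaves(self) -> list[int]:
        return sorted((n for n, nb in self.adj.items() if len(nb) <= 1),
                      key=lambda n: self.labels.get(n, ""))

    def leaf_names(self) -> list[str]:
        return sorted(self.labels[n] for n in self.leaves())

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in sorted(self.adj):
            for v in sorted(self.adj[u]):
                if u < v:
                    out.append((u, v))
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf labels in the component containing u after cutting (u,v)."""
        seen = {v, u}
        stack = [u]
        names = set()
        while stack:
            x = stack.pop()
            if x in self.labels:
                names.add(self.labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return names

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the side not containing the
        lexicographically smallest leaf label."""
        all_names = set(self.leaf_names())
        ref = min(all_names)
        out: set[frozenset[str]] = set()
        for u, v in self.edges():
            side = self._side_leaves(u, v)
            if ref in side:
                side = all_names - side
            if 2 <= len(side) <= len(all_names) - 2:
                out.add(frozenset(side))
        return out

    # -- newick -----------------------------------------------------------
    def newick(self, with_lengths: bool = True) -> str:
        leaves = self.leaves()
        if len(leaves) == 1:
            return f"{self.labels[leaves[0]]};"
        root = leaves[0]  # root at smallest-labelled leaf for canonical form

        def fmt(u: int, parent: int) -> tuple[str, str]:
            kids = sorted(self.adj[u] - {parent})
            if not kids:
                return self.labels.get(u, str(u)), self.labels.get(u, "")
            rendered = []
            label = None
            for kk in kids:
                txt, key = fmt(kk, u)
                label = key if label is None else min(label, key)
                if with_lengths:
                    ln = self.lengths.get(frozenset((u, kk)))
                    if ln is not None:
                        txt = f"{txt}:{ln:.6f}"
                rendered.append((key, txt))
            rendered.sort()
            return "(" + ",".join(t for _, t in rendered) + ")", label

        body, _ = fmt(next(iter(self.adj[root])), root)
        name = self.labels[root]
        ln = ""
        if with_lengths:
            e = frozenset((root, next(iter(self.adj[root]))))
            if e in self.lengths:
                ln = f":{self.lengths[e]:.6f}"
        return f"({name}{ln},{body[1:-1] if body.startswith('(') else body});"

    def canonical(self) -> str:
        """Topology-only canonical string for deduplication."""
        return self.newick(with_lengths=False)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy
        dt = dendropy.Tree.get(data=newick, schema="newick")
        dt.deroot()
        t = cls()
        node_map = {}
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon else None
            node_map[nd] = t.new_node(label)
        for nd in dt.preorder_node_iter():
            if nd.parent_node is not None:
                t.add_edge(node_map[nd.parent_node], node_map[nd],
                           nd.edge.length)
        # suppress any residual degree-2 nodes from rooting
        for n in [n for n, nb in t.adj.items() if len(nb) == 2 and n not in t.labels]:
            a, b = sorted(t.adj[n])
            la = t.lengths.get(frozenset((n, a)), 0.0) or 0.0
            lb = t.lengths.get(frozenset((n, b)), 0.0) or 0.0
            t.remove_edge(n, a)
            t.remove_edge(n, b)
            t.add_edge(a, b, la + lb)
            del t.adj[n]
        return t


@dataclass
class SearchResult:
    best_length: float
    best_trees: list[Tree]
    replicate_lengths: list[float]

    @property
    def n_best(self) -> int:
        return len(self.best_trees)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Classical NJ; deterministic lexicographic tie-breaking."""
    ids = list(dm.ids)
    if len(ids) < 3:
        raise InputError("NJ needs at least 3 taxa")
    iu = np.triu_indices(len(ids), k=1)
    if not dm.defined[iu].all():
        bad = [(ids[i], ids[j]) for i, j in zip(*iu) if not dm.defined[i, j]]
        raise InputError(f"undefined distances for pairs: {bad}")
    t = Tree()
    nodes = [t.new_node(i) for i in ids]
    keys = list(ids)  # min leaf label per cluster, for tie-breaking
    D = dm.matrix.astype(float).copy()
    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                cand = (q, min(keys[i], keys[j]), max(keys[i], keys[j]), i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        vi = (D[i, j] + (r[i] - r[j]) / (n - 2)) / 2.0
        vj = D[i, j] - vi
        new = t.new_node()
        t.add_edge(new, nodes[i], vi)
        t.add_edge(new, nodes[j], vj)
        newrow = np.array([(D[i, k] + D[j, k] - D[i, j]) / 2.0
                           for k in range(n) if k not in (i, j)])
        keep = [k for k in range(n) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.vstack([np.hstack([D, newrow[:, None]]),
                       np.hstack([newrow, [0.0]])])
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
    t.add_edge(nodes[0], nodes[1], max(D[0, 1], 0.0))
    return t


# ---------------------------------------------------------------------------
# Parsimony scoring
# ---------------------------------------------------------------------------

@dataclass
class _Encoded:
    ids: list[str]
    unordered: np.ndarray  # (n_taxa, n_unordered) bitmasks, uint32
    full_masks: np.ndarray  # (n_unordered,) all-states mask per character
    sankoff: list[tuple[np.ndarray, dict[str, int | None]]]
    # observed symbols for CI/RI
    unordered_symbols: list[dict[str, int]]  # taxon -> state index (missing absent)
    n_dna: int


def _encode(cm: CodedMatrix) -> _Encoded:
    aln = cm.alignment
    ids = list(aln.ids)
    cols: list[np.ndarray] = []
    fulls: list[int] = []
    symbols: list[dict[str, int]] = []
    arr = aln.array
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j in range(aln.length):
        col = arr[:, j]
        cols.append(np.array([_DNA_BITS[c] for c in col], dtype=np.uint32))
        fulls.append(15)
        symbols.append({ids[r]: base_idx[c] for r, c in enumerate(col)
                        if c in base_idx})
    sankoff: list[tuple[np.ndarray, dict[str, int | None]]] = []
    for ch in cm.coded:
        if ch.step_matrix is None:
            k = len(ch.symbols)
            full = (1 << k) - 1
            masks = []
            sym: dict[str, int] = {}
            for sid in ids:
                s = ch.states.get(sid, "?")
                if s == "?":
                    masks.append(full)
                else:
                    masks.append(1 << int(s))
                    sym[sid] = int(s)
            cols.append(np.array(masks, dtype=np.uint32))
            fulls.append(full)
            symbols.append(sym)
        else:
            states: dict[str, int | None] = {}
            for sid in ids:
                s = ch.states.get(sid, "?")
                states[sid] = None if s == "?" else int(s)
            sankoff.append((ch.step_matrix.astype(float), states))
    unordered = (np.stack(cols, axis=1) if cols
                 else np.zeros((len(ids), 0), dtype=np.uint32))
    return _Encoded(ids, unordered, np.array(fulls, dtype=np.uint32),
                    sankoff, symbols, aln.length)


def _rooted_postorder(tree: Tree) -> tuple[int, int, list[tuple[int, list[int]]]]:
    """Root at the smallest-labelled leaf; return (root leaf, its neighbor,
    postorder list of (node, children)) over the rest of the tree."""
    leaves = tree.leaves()
    root = leaves[0]
    (top,) = tree.adj[root]
    order: list[tuple[int, list[int]]] = []
    stack = [(top, root, False)]
    while stack:
        node, parent, done = stack.pop()
        kids = sorted(tree.adj[node] - {parent})
        if done or not kids:
            order.append((node, kids))
        else:
            stack.append((node, parent, True))
            for k in kids:
                stack.append((k, node, False))
    return root, top, order


def _fitch_steps(tree: Tree, enc: _Encoded,
                 weights: np.ndarray | None) -> tuple[float, np.ndarray]:
    """Total weighted Fitch steps and the per-character step vector for the
    unordered characters."""
    nchar = enc.unordered.shape[1]
    steps = np.zeros(nchar)
    if nchar == 0:
        return 0.0, steps
    idx = {sid: r for r, sid in enumerate(enc.ids)}
    root, top, order = _rooted_postorder(tree)
    masks: dict[int, np.ndarray] = {}
    for node, kids in order:
        if not kids:
            masks[node] = enc.unordered[idx[tree.labels[node]]]
            continue
        m = masks[kids[0]]
        for k in kids[1:]:
            inter = m & masks[k]
            empty = inter == 0
            steps += empty
            m = np.where(empty, m | masks[k], inter)
        masks[node] = m
    # fold the root leaf
    rmask = enc.unordered[idx[tree.labels[root]]]
    inter = masks[top] & rmask
    steps += inter == 0
    if weights is not None:
        w = weights[:nchar]
        return float(steps @ w), steps
    return float(steps.sum()), steps


def _sankoff_steps(tree: Tree, enc: _Encoded,
                   weights: np.ndarray | None) -> tuple[float, list[float]]:
    if not enc.sankoff:
        return 0.0, []
    root, top, order = _rooted_postorder(tree)
    per: list[float] = []
    total = 0.0
    nchar_u = enc.unordered.shape[1]
    INF = math.inf
    for ci, (step, states) in enumerate(enc.sankoff):
        k = step.shape[0]

        def leaf_cost(node: int) -> np.ndarray:
            s = states[tree.labels[node]]
            if s is None:
                return np.zeros(k)
            c = np.full(k, INF)
            c[s] = 0.0
            return c

        costs: dict[int, np.ndarray] = {}
        for node, kids in order:
            if not kids:
                costs[node] = leaf_cost(node)
                continue
            c = np.zeros(k)
            for kid in kids:
                cc = costs[kid]
                c += (step + cc[None, :]).min(axis=1)
            costs[node] = c
        rc = leaf_cost(root)
        final = costs[top] + (step + rc[None, :]).min(axis=1)
        s = float(final.min())
        per.append(s)
        w = 1.0 if weights is None else float(weights[nchar_u + ci])
        total += w * s
    return total, per


def parsimony_length(tree: Tree, cm: CodedMatrix,
                     weights: np.ndarray | None = None) -> float:
    """Parsimony tree length: Fitch for unordered characters, Sankoff for
    step-matrix characters.  ``weights`` (character resampling counts) must
    cover nucleotide columns, unordered coded and Sankoff coded characters
    in that order."""
    if set(tree.leaf_names()) != set(cm.alignment.ids):
        raise InputError("tree leaves do not match matrix ids")
    enc = _encode(cm)
    f, _ = _fitch_steps(tree, enc, weights)
    s, _ = _sankoff_steps(tree, enc, weights)
    return f + s


def per_character_steps(tree: Tree, cm: CodedMatrix) -> np.ndarray:
    """Observed steps per character (unordered then Sankoff order)."""
    enc = _encode(cm)
    _, fv = _fitch_steps(tree, enc, None)
    _, sv = _sankoff_steps(tree, enc, None)
    return np.concatenate([fv, np.array(sv)]) if sv else fv


# ---------------------------------------------------------------------------
# Heuristic MP search
# ---------------------------------------------------------------------------

def _insert_leaf(tree: Tree, name: str, edge: tuple[int, int]) -> int:
    u, v = edge
    tree.remove_edge(u, v)
    mid = tree.new_node()
    leaf = tree.new_node(name)
    tree.add_edge(u, mid)
    tree.add_edge(mid, v)
    tree.add_edge(mid, leaf)
    return leaf


def _score_fn(cm: CodedMatrix, weights: np.ndarray | None):
    enc = _encode(cm)

    def score(tree: Tree) -> float:
        f, _ = _fitch_steps(tree, enc, weights)
        s, _ = _sankoff_steps(tree, enc, weights)
        return f + s

    return score


def _stepwise_addition(names: list[str], score) -> Tree:
    t = Tree()
    a = t.new_node(names[0])
    b = t.new_node(names[1])
    c = t.new_node(names[2])
    mid = t.new_node()
    for leaf in (a, b, c):
        t.add_edge(mid, leaf)
    for name in names[3:]:
        best = None
        for edge in t.edges():
            cand = t.copy()
            _insert_leaf(cand, name, edge)
            s = score(cand)
            if best is None or s < best[0]:
                best = (s, cand)
        t = best[1]
    return t


def _nni_neighbors(tree: Tree):
    for u, v in tree.edges():
        if u in tree.labels or v in tree.labels:
            continue
        (a, b) = sorted(tree.adj[u] - {v})[:2]
        others = sorted(tree.adj[v] - {u})
        for c in others:
            t = tree.copy()
            t.remove_edge(u, b)
            t.remove_edge(v, c)
            t.add_edge(u, c)
            t.add_edge(v, b)
            yield t


def _prune(tree: Tree, u: int, v: int) -> tuple[Tree, int, set[int]] | None:
    """Cut edge (u,v); the component of u becomes the pruned subtree with
    attachment node u.  Returns (modified copy, attachment node, node set of
    the pruned side) or None when the move is degenerate."""
    t = tree.copy()
    t.remove_edge(u, v)
    # collect pruned side
    side = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in t.adj[x]:
            if y not in side:
                side.add(y)
                stack.append(y)
    rest = set(t.adj) - side
    if len(rest) < 2 or len(side) < 1:
        return None
    # suppress v if it became degree-2 internal
    if v not in t.labels and len(t.adj[v]) == 2:
        a, b = sorted(t.adj[v])
        t.remove_edge(v, a)
        t.remove_edge(v, b)
        t.add_edge(a, b)
        del t.adj[v]
        rest.discard(v)
    # remaining tree must still have an edge to regraft onto
    if sum(1 for x, y in t.edges() if x in rest and y in rest) < 1:
        return None
    return t, u, side


def _regraft(t: Tree, attach: int, edge: tuple[int, int]) -> Tree:
    """Reconnect a pruned subtree (hanging from ``attach``) into ``edge``
    via a fresh internal node, keeping the tree binary."""
    out = t.copy()
    x, y = edge
    out.remove_edge(x, y)
    mid = out.new_node()
    out.add_edge(x, mid)
    out.add_edge(mid, y)
    out.add_edge(mid, attach)
    return out


def _spr_neighbors(tree: Tree, tbr: bool = False):
    for u, v in itertools.chain(tree.edges(),
                                [(b, a) for a, b in tree.edges()]):
        pruned = _prune(tree, u, v)
        if pruned is None:
            continue
        t, attach, side = pruned
        rest_edges = [(x, y) for x, y in t.edges()
                      if x not in side and y not in side]
        attach_points = [attach]
        if tbr:
            # reroot the pruned subtree at each of its internal edges
            side_edges = [(x, y) for x, y in t.edges()
                          if x in side and y in side]
            for x, y in side_edges:
                t2 = t.copy()
                # free the old attachment if it is a degree-2 internal node
                if attach not in t2.labels and len(t2.adj[attach]) == 2:
                    a, b = sorted(t2.adj[attach])
                    t2.remove_edge(attach, a)
                    t2.remove_edge(attach, b)
                    t2.add_edge(a, b)
                    del t2.adj[attach]
                if y not in t2.adj.get(x, set()):
                    continue  # edge vanished when the old attachment collapsed
                t2.remove_edge(x, y)
                new_attach = t2.new_node()
                t2.add_edge(x, new_attach)
                t2.add_edge(new_attach, y)
                for edge in rest_edges:
                    yield _regraft(t2, new_attach, edge)
        for edge in rest_edges:
            yield _regraft(t, attach, edge)


def _swap_neighbors(tree: Tree, swap: str):
    swap = swap.upper()
    if swap == "NNI":
        yield from _nni_neighbors(tree)
    elif swap == "SPR":
        yield from _spr_neighbors(tree, tbr=False)
    elif swap == "TBR":
        yield from _spr_neighbors(tree, tbr=True)
    else:
        raise InputError(f"unknown swap strategy {swap!r}")


def mp_search(cm: CodedMatrix, n_additions: int = 10, swap: str = "TBR",
              keep: int = 100, seed: int | None = None,
              weights: np.ndarray | None = None) -> SearchResult:
    """Random-addition + branch-swapping heuristic parsimony search."""
    names = sorted(cm.alignment.ids)
    if len(names) < 4:
        raise InputError("MP search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    score = _score_fn(cm, weights)
    best_len = math.inf
    buffer: dict[str, Tree] = {}
    rep_lengths: list[float] = []
    for _ in range(n_additions):
        order = [names[i] for i in rng.permutation(len(names))]
        tree = _stepwise_addition(order, score)
        cur = score(tree)
        improved = True
        while improved:
            improved = False
            for cand in _swap_neighbors(tree, swap):
                s = score(cand)
                if s < cur - 1e-9:
                    tree, cur = cand, s
                    improved = True
                    break
        rep_lengths.append(cur)
        if cur < best_len - 1e-9:
            best_len = cur
            buffer = {tree.canonical(): tree}
        elif abs(cur - best_len) <= 1e-9 and len(buffer) < keep:
            buffer.setdefault(tree.canonical(), tree)
    return SearchResult(best_len, list(buffer.values()), rep_lengths)


# ---------------------------------------------------------------------------
# CI / RI
# ---------------------------------------------------------------------------

def _shortest_path_closure(step: np.ndarray) -> np.ndarray:
    d = step.copy()
    k = d.shape[0]
    for m in range(k):
        d = np.minimum(d, d[:, m:m + 1] + d[m:m + 1, :])
    return d


def _mst_weight(dist: np.ndarray) -> float:
    """Prim's MST over a small complete graph."""
    n = dist.shape[0]
    if n <= 1:
        return 0.0
    in_tree = [0]
    out = set(range(1, n))
    total = 0.0
    while out:
        best = min(((dist[i, j], j) for i in in_tree for j in out))
        total += best[0]
        in_tree.append(best[1])
        out.remove(best[1])
    return total


def ci_ri(tree: Tree, cm: CodedMatrix) -> tuple[float, float]:
    """Ensemble consistency and retention indices.

    CI = sum(m_i)/sum(s_i); RI = (sum(g_i)-sum(s_i))/(sum(g_i)-sum(m_i)),
    where m_i is the minimum conceivable steps of character i on any tree,
    s_i the observed steps, and g_i the maximum steps (star tree).
    RI is nan when sum(g) == sum(m).
    """
    enc = _encode(cm)
    steps = per_character_steps(tree, cm)
    m_sum = s_sum = g_sum = 0.0
    # unordered characters
    for i, sym in enumerate(enc.unordered_symbols):
        if not sym:
            continue
        counts: dict[int, int] = {}
        for st in sym.values():
            counts[st] = counts.get(st, 0) + 1
        nstates = len(counts)
        m = nstates - 1
        g = sum(counts.values()) - max(counts.values())
        m_sum += m
        s_sum += steps[i]
        g_sum += g
    # Sankoff characters
    off = enc.unordered.shape[1]
    for ci, (step, states) in enumerate(enc.sankoff):
        obs = [s for s in states.values() if s is not None]
        if not obs:
            continue
        d = _shortest_path_closure(step)
        uniq = sorted(set(obs))
        m = _mst_weight(d[np.ix_(uniq, uniq)])
        g = min(sum(d[s, c] for s in obs) for c in range(step.shape[0]))
        m_sum += m
        s_sum += steps[off + ci]
        g_sum += g
    ci_val = m_sum / s_sum if s_sum > 0 else math.nan
    ri_val = ((g_sum - s_sum) / (g_sum - m_sum)
              if g_sum - m_sum > 0 else math.nan)
    return ci_val, ri_val


# ---------------------------------------------------------------------------
# Bootstrap + majority-rule consensus
# ---------------------------------------------------------------------------

def _tree_from_clusters(names: list[str],
                        clusters: list[tuple[frozenset[str], float]]) -> Tree:
    """Build a tree from compatible nested clusters (greedy, largest first)."""
    t = Tree()
    root = t.new_node()
    parent: dict[str, int] = {}
    leaf_id: dict[str, int] = {}
    for nm in names:
        nid = t.new_node(nm)
        t.add_edge(root, nid)
        parent[nm] = root
        leaf_id[nm] = nid
    for cluster, support in sorted(clusters, key=lambda c: -len(c[0])):
        holders = {parent[nm] for nm in cluster}
        if len(holders) != 1:
            continue  # incompatible with what is already built; skip
        p = holders.pop()
        node = t.new_node()
        t.add_edge(p, node)
        for nm in cluster:
            t.remove_edge(p, leaf_id[nm])
            t.add_edge(node, leaf_id[nm])
            parent[nm] = node
        t.supports[cluster] = support
    return t


def bootstrap_consensus(cm: CodedMatrix, n_reps: int = 100,
                        threshold: float = 85.0, seed: int | None = None,
                        n_additions: int = 1, swap: str = "NNI",
                        ) -> tuple[Tree, dict[frozenset[str], float]]:
    """Character bootstrap with a reduced per-replicate search and a
    majority-rule consensus of splits at >= ``threshold`` percent."""
    rng = np.random.default_rng(seed)
    total = cm.total_characters
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        weights = rng.multinomial(total, np.full(total, 1.0 / total)).astype(float)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        res = mp_search(cm, n_additions=n_additions, swap=swap, keep=1,
                        seed=rep_seed, weights=weights)
        for bp in res.best_trees[0].bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    kept = [(bp, s) for bp, s in supports.items() if s >= threshold]
    names = sorted(cm.alignment.ids)
    consensus = _tree_from_clusters(names, kept)
    return consensus, supports


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric bipartition distance between two unrooted trees."""
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)
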