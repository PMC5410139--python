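"""Fitch parsimony: site classification, tree length, CI/RI, heuristic search.

Gaps and ambiguity characters are treated as missing data.  Tree length is
the sum over sites of the Fitch (unordered, equal-cost) minimum number of
changes; the consistency index CI is the ratio of the per-site minimum
conceivable changes to the realized length, and the retention index RI
measures how much potential homoplasy the tree avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, BASES
from .errors import TreeError
from .trees import read_newick

_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING_BITS = 15


def encode_states(a: Alignment) -> np.ndarray:
    """Bitmask encoding of the alignment (missing -> all four bits set)."""
    codes = np.full(a.matrix.shape, _MISSING_BITS, dtype=np.uint8)
    for base, bit in _STATE_BITS.items():
        codes[a.matrix == base] = bit
    return codes


def classify_sites(a: Alignment) -> tuple[int, int, int]:
    """Counts of (constant, parsimony-informative, variable-uninformative) sites.

    A site is informative when at least two states each occur in at least two
    sequences; gaps/ambiguities are ignored when counting states.
    """
    n_const = n_inf = n_uninf = 0
    for col in a.matrix.T:
        counts = [int(np.sum(col == b)) for b in BASES]
        present = [c for c in counts if c > 0]
        if len(present) <= 1:
            n_const += 1
        elif sum(1 for c in present if c >= 2) >= 2:
            n_inf += 1
        else:
            n_uninf += 1
    return n_const, n_inf, n_uninf


@dataclass
class ParsimonyResult:
    length: int
    ci: float
    ri: float
    per_site_steps: np.ndarray
    per_site_min: np.ndarray


def _per_site_min_max(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site minimum conceivable steps and maximum steps on any tree."""
    n, L = codes.shape
    mins = np.zeros(L, dtype=int)
    maxs = np.zeros(L, dtype=int)
    for s in range(L):
        col = codes[:, s]
        unamb = col[col != _MISSING_BITS]
        counts = [int(np.sum(unamb == bit)) for bit in _STATE_BITS.values()]
        present = [c for c in counts if c > 0]
        if present:
            mins[s] = len(present) - 1
            maxs[s] = sum(present) - max(present)
    return mins, maxs


class _Topology:
    """Unrooted binary tree over leaf ids 0..n-1 as an adjacency map."""

    def __init__(self, adj: dict[int, list[int]], n_leaves: int):
        self.adj = adj
        self.n_leaves = n_leaves

    @classmethod
    def initial(cls, l0: int, l1: int, l2: int) -> "_Topology":
        v = max(l0, l1, l2) + 1_000_000  # internal ids offset past any leaf id
        adj = {l0: [v], l1: [v], l2: [v], v: [l0, l1, l2]}
        return cls(adj, 3)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def copy(self) -> "_Topology":
        return _Topology({u: list(v) for u, v in self.adj.items()}, self.n_leaves)

    def insert_leaf(self, leaf: int, edge: tuple[int, int]) -> "_Topology":
        t = self.copy()
        u, v = edge
        w = max(t.adj) + 1
        t.adj[u][t.adj[u].index(v)] = w
        t.adj[v][t.adj[v].index(u)] = w
        t.adj[w] = [u, v, leaf]
        t.adj[leaf] = [w]
        t.n_leaves += 1
        return t

    def splits(self) -> frozenset[frozenset[int]]:
        """Non-trivial bipartitions, each as the side not containing min leaf."""
        leaves = frozenset(x for x in self.adj if len(self.adj[x]) == 1)
        anchor = min(leaves)
        out = set()
        for u, v in self.edges():
            side = frozenset(self._leaves_beyond(u, v))
            if 1 < len(side) < len(leaves) - 1:
                if anchor in side:
                    side = leaves - side
                out.add(side)
        return frozenset(out)

    def _leaves_beyond(self, u: int, v: int) -> list[int]:
        """Leaf ids on the v side of edge (u, v)."""
        stack, seen, leaves = [v], {u, v}, []
        while stack:
            x = stack.pop()
            if len(self.adj[x]) == 1:
                leaves.append(x)
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return leaves

    def nni_neighbours(self) -> list["_Topology"]:
        out = []
        for u, v in self.edges():
            if len(self.adj[u]) == 1 or len(self.adj[v]) == 1:
                continue  # needs both endpoints internal
            a, b = [x for x in self.adj[u] if x != v]
            c, d = [x for x in self.adj[v] if x != u]
            for x, y in ((b, c), (b, d)):
                t = self.copy()
                t.adj[u][t.adj[u].index(x)] = y
                t.adj[y][t.adj[y].index(v)] = u
                t.adj[v][t.adj[v].index(y)] = x
                t.adj[x][t.adj[x].index(u)] = v
                out.append(t)
        return out

    def to_newick(self, labels: list[str]) -> str:
        start = min(l for l in self.adj if len(self.adj[l]) == 1)
        root = self.adj[start][0]

        def sub(node: int, parent: int) -> str:
            if len(self.adj[node]) == 1:
                return labels[node]
            parts = [sub(c, node) for c in self.adj[node] if c != parent]
            return "(" + ",".join(parts) + ")"

        parts = [labels[start]] + [sub(c, root) for c in self.adj[root] if c != start]
        return "(" + ",".join(parts) + ");"


def _fitch_steps(topo: _Topology, codes: np.ndarray) -> tuple[int, np.ndarray]:
    """Fitch length of a topology; leaves of the topology index rows of codes."""
    L = codes.shape[1]
    steps = np.zeros(L, dtype=np.int64)
    start = min(l for l in topo.adj if len(topo.adj[l]) == 1)
    root = topo.adj[start][0]

    def down(node: int, parent: int) -> np.ndarray:
        if len(topo.adj[node]) == 1:
            return codes[node]
        cur = None
        for c in topo.adj[node]:
            if c == parent:
                continue
            child = down(c, node)
            if cur is None:
                cur = child.copy()
            else:
                inter = cur & child
                empty = inter == 0
                steps[empty] += 1
                cur = np.where(empty, cur | child, inter)
        return cur

    root_set = down(root, start)
    inter = root_set & codes[start]
    empty = inter == 0
    steps[empty] += 1
    return int(steps.sum()), steps


def fitch_length(tree, a: Alignment) -> ParsimonyResult:
    """Score a tree by Fitch parsimony and report length, CI and RI.

    ``tree`` is a dendropy Tree (or Newick string/path) whose leaf labels
    match the alignment ids exactly.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if set(labels) != set(a.ids):
        raise TreeError(
            "tree leaf labels do not match alignment ids: "
            f"extra={sorted(set(labels) - set(a.ids))}, "
            f"missing={sorted(set(a.ids) - set(labels))}"
        )
    codes = encode_states(a)
    row = {sid: i for i, sid in enumerate(a.ids)}

    L = a.length
    steps = np.zeros(L, dtype=np.int64)

    def down(node) -> np.ndarray:
        if node.is_leaf():
            return codes[row[node.taxon.label]]
        cur = None
        for c in node.child_nodes():
            child = down(c)
            if cur is None:
                cur = child.copy()
            else:
                inter = cur & child
                empty = inter == 0
                steps[empty] += 1
                cur = np.where(empty, cur | child, inter)
        return cur

    down(tree.seed_node)
    length = int(steps.sum())
    mins, maxs = _per_site_min_max(codes)
    ci = 1.0 if length == 0 else float(mins.sum()) / length
    denom = maxs.sum() - mins.sum()
    ri = 1.0 if denom == 0 else float(maxs.sum() - length) / denom
    return ParsimonyResult(
        length=length, ci=ci, ri=ri, per_site_steps=steps, per_site_min=mins
    )


@dataclass
class ParsimonySearchResult:
    length: int
    trees: list  # dendropy Trees
    newicks: list[str]


def parsimony_search(
    a: Alignment, seed: int = 0, search_factor: int = 1
) -> ParsimonySearchResult:
    """Heuristic maximum-parsimony search (stepwise addition + NNI).

    Taxa are added in label order; at each addition step all placements
    scoring within ``search_factor`` of the current best are retained
    (a min-mini-flavoured beam).  Retained full trees are refined by NNI
    hill-climbing and all distinct topologies at the best length found are
    returned.  Deterministic given the seed (used only to cap the beam when
    it grows very large).
    """
    if a.n < 4:
        raise TreeError("parsimony search requires at least 4 sequences")
    rng = np.random.default_rng(seed)
    order = sorted(range(a.n), key=lambda i: a.ids[i])
    codes = encode_states(a)

    beam = [_Topology.initial(order[0], order[1], order[2])]
    for leaf in order[3:]:
        candidates = []
        for topo in beam:
            for edge in topo.edges():
                t = topo.insert_leaf(leaf, edge)
                s, _ = _fitch_steps(t, codes)
                candidates.append((s, t))
        best = min(s for s, _ in candidates)
        kept = [t for s, t in candidates if s <= best + search_factor]
        if len(kept) > 200:  # cap beam; keep a deterministic random subset
            keep_idx = rng.choice(len(kept), size=200, replace=False)
            kept = [kept[i] for i in sorted(keep_idx)]
        beam = _dedupe(kept)

    # NNI refinement of every retained tree
    refined: list[tuple[int, _Topology]] = []
    for topo in beam:
        s, _ = _fitch_steps(topo, codes)
        improved = True
        while improved:
            improved = False
            for t in topo.nni_neighbours():
                s2, _ = _fitch_steps(t, codes)
                if s2 < s:
                    topo, s = t, s2
                    improved = True
                    break
        refined.append((s, topo))
    best = min(s for s, _ in refined)
    # sweep NNI neighbourhoods of optimal trees to collect co-optimal topologies
    optimal = _dedupe([t for s, t in refined if s == best])
    frontier = list(optimal)
    seen = {t.splits() for t in optimal}
    while frontier:
        nxt = []
        for topo in frontier:
            for t in topo.nni_neighbours():
                key = t.splits()
                if key in seen:
                    continue
                s2, _ = _fitch_steps(t, codes)
                if s2 == best:
                    seen.add(key)
                    optimal.append(t)
                    nxt.append(t)
        frontier = nxt
    newicks = [t.to_newick(a.ids) for t in optimal]
    trees = [read_newick(nw) for nw in newicks]
    return ParsimonySearchResult(length=best, trees=trees, newicks=newicks)


def _dedupe(topos: list[_Topology]) -> list[_Topology]:
    seen, out = set(), []
    for t in topos:
        key = t.splits()
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out
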