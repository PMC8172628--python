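"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the definitions, without reusing
any code path of the package under test.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# local affine-gap alignment by enumeration over substring pairs
# ---------------------------------------------------------------------------


def global_affine_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score of two (short) strings, by recursion from
    the definition: at each step align a residue pair, or open/extend a gap.
    A gap of length k costs gap_open + (k-1)*gap_extend."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + f(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open
            best = max(best, cost + f(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open
            best = max(best, cost + f(i, j + 1, "B"))
        return best

    return f(0, 0, "M")


def local_affine_oracle(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Best local score = max over all substring pairs of their global score
    (and 0 for the empty alignment)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_affine_score(
                        a[i1:i2], b[j1:j2], sub, gap_open, gap_extend
                    )
                    if s > best:
                        best = s
    return best


# ---------------------------------------------------------------------------
# birth-death lineage counting (no sequences)
# ---------------------------------------------------------------------------


def bd_leaf_counts(branches, b: float, d: float, rng: np.random.Generator) -> dict[str, int]:
    """Simulate pure lineage birth-death along a tree given as nested dicts:
    ``{"name": str, "length": float, "children": [...]}`` (root length 0).
    Returns surviving lineage count per leaf name."""

    counts: dict[str, int] = {}

    def evolve_one(time_left: float) -> int:
        # returns number of surviving lineages descending from one lineage
        total = b + d
        if total <= 0:
            return 1
        t = rng.exponential(1.0 / total)
        if t >= time_left:
            return 1
        if rng.random() < b / total:
            return evolve_one(time_left - t) + evolve_one(time_left - t)
        return 0

    def walk(node, n_in: int):
        n_out = sum(evolve_one(node["length"]) for _ in range(n_in))
        if not node["children"]:
            counts[node["name"]] = n_out
        else:
            for ch in node["children"]:
                walk(ch, n_out)

    root = branches
    if not root["children"]:
        counts[root["name"]] = 1
    else:
        for ch in root["children"]:
            walk(ch, 1)
    return counts


# ---------------------------------------------------------------------------
# Dollo parsimony by exhaustive gain enumeration
# ---------------------------------------------------------------------------


def dollo_oracle(node, present: set[str]):
    """Minimal single-gain explanation by enumerating every possible gain node.

    ``node`` is a nested tuple tree: leaves are strings, internal nodes are
    tuples of children. Returns ``(min_losses, gain_leafsets)`` where
    ``gain_leafsets`` are the leaf sets of all gain nodes achieving the
    minimum.
    """

    def leaves(n):
        if isinstance(n, str):
            return {n}
        out = set()
        for c in n:
            out |= leaves(c)
        return out

    def count_losses(n) -> int:
        # losses needed below a gained node: each maximal all-absent subtree is one loss
        lv = leaves(n)
        if not (lv & present):
            return 1
        if isinstance(n, str):
            return 0
        return sum(count_losses(c) for c in n)

    candidates = []

    def visit(n):
        if leaves(n) >= present:
            candidates.append((count_losses(n), frozenset(leaves(n))))
        if not isinstance(n, str):
            for c in n:
                visit(c)

    visit(node)
    best = min(c[0] for c in candidates)
    return best, {ls for cost, ls in candidates if cost == best}


def all_rooted_shapes(n: int):
    """All rooted binary tree shapes with n leaves, as nested tuples of leaf
    count placeholders; leaves are filled in later."""
    if n == 1:
        return [None]
    shapes = []
    seen = set()
    for k in range(1, n // 2 + 1):
        for left in all_rooted_shapes(k):
            for right in all_rooted_shapes(n - k):
                key = (repr(left), repr(right))
                key = tuple(sorted(key))
                if key in seen:
                    continue
                seen.add(key)
                shapes.append((left, right))
    return shapes


def label_shape(shape, prefix: str = "s"):
    """Fill a shape's leaves with s1..sN in left-to-right order."""
    counter = itertools.count(1)

    def fill(n):
        if n is None:
            return f"{prefix}{next(counter)}"
        return tuple(fill(c) for c in n)

    return fill(shape)


def shape_to_newick(t) -> str:
    def fmt(n):
        if isinstance(n, str):
            return f"{n}:1.0"
        return "(" + ",".join(fmt(c) for c in n) + "):1.0"

    if isinstance(t, str):
        return t + ";"
    return "(" + ",".join(fmt(c) for c in t) + ");"


# ---------------------------------------------------------------------------
# unrooted topology enumeration + additive distances (for neighbor-joining)
# ---------------------------------------------------------------------------


class UnrootedTopology:
    """Unrooted binary tree over named leaves, as an adjacency structure."""

    def __init__(self, taxa3):
        a, b, c = taxa3
        self.adj = {0: {a, b, c}, a: {0}, b: {0}, c: {0}}
        self.next_internal = 1

    def copy(self):
        new = object.__new__(UnrootedTopology)
        new.adj = {k: set(v) for k, v in self.adj.items()}
        new.next_internal = self.next_internal
        return new

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    yield (u, v)

    def insert_leaf(self, taxon, edge):
        u, v = edge
        w = self.next_internal
        self.next_internal += 1
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self.adj[w] = {u, v, taxon}
        self.adj[u].add(w)
        self.adj[v].add(w)
        self.adj[taxon] = {w}

    def leaf_names(self):
        return sorted(k for k in self.adj if isinstance(k, str))

    def splits(self):
        """Non-trivial bipartitions as frozensets not containing the smallest leaf."""
        leaves = set(self.leaf_names())
        ref = min(leaves)
        out = set()
        for u, v in self.edges():
            if isinstance(u, str) or isinstance(v, str):
                continue
            side = self._component_leaves(u, v)
            if ref in side:
                side = leaves - side
            if 1 < len(side) < len(leaves) - 1:
                out.add(frozenset(side))
        return out

    def _component_leaves(self, start, blocked):
        stack, seen, leaves = [start], {start, blocked}, set()
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                leaves.add(x)
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return leaves

    def additive_matrix(self, rng: np.random.Generator):
        lengths = {frozenset(e): float(rng.uniform(0.2, 2.0)) for e in self.edges()}
        names = self.leaf_names()
        n = len(names)
        d = np.zeros((n, n))
        for i, a in enumerate(names):
            for j in range(i + 1, n):
                b = names[j]
                d[i, j] = d[j, i] = self._path_len(a, b, lengths)
        return names, d

    def _path_len(self, a, b, lengths):
        # BFS path
        prev = {a: None}
        stack = [a]
        while stack:
            x = stack.pop(0)
            if x == b:
                break
            for y in self.adj[x]:
                if y not in prev:
                    prev[y] = x
                    stack.append(y)
        total = 0.0
        x = b
        while prev[x] is not None:
            total += lengths[frozenset((x, prev[x]))]
            x = prev[x]
        return total


def all_unrooted_topologies(taxa: list[str]):
    """Every unrooted binary topology over the taxa (3, 15, 105, ... trees)."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    trees = [UnrootedTopology(taxa[:3])]
    for taxon in taxa[3:]:
        nxt = []
        for t in trees:
            for edge in list(t.edges()):
                t2 = t.copy()
                t2.insert_leaf(taxon, edge)
                nxt.append(t2)
        trees = nxt
    return trees


# ---------------------------------------------------------------------------
# loop-based motif oracles (no regular expressions)
# ---------------------------------------------------------------------------

ALIPHATIC = set("AVIL")
CAAX_LAST = set("STQAM")


def caax_oracle(seq: str):
    s = seq.upper()
    if len(s) < 4:
        return None
    tail = s[-4:]
    if tail[0] == "C" and tail[1] in ALIPHATIC and tail[2] in ALIPHATIC and tail[3] in CAAX_LAST:
        return len(s) - 3
    return None


def wxxxfy_oracle(seq: str):
    s = seq.upper()
    out = []
    for i in range(len(s) - 4):
        if s[i] == "W" and s[i + 4] in ("F", "Y"):
            out.append(i + 1)
    return out
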