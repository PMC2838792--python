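"""Character-based behavioral networks: parsimony scoring and tree search.

Individuals are the leaves of an unrooted tree; each behavioral symptom is a
character. Dichotomous symptoms are scored as unordered binary characters
(Fitch), four-state severity scales as ordered characters with cost ``|i-j|``
(Wagner); missing states are free. The shortest tree groups individuals with
shared symptom profiles, and a majority-rule consensus summarizes the set of
equally parsimonious trees that heuristic search returns.

Search is a Nixon-style parsimony ratchet (alternating hill climbs on
reweighted and original characters) with NNI rearrangements, plus an SPR
hill-climbing refinement pass intended for re-analysis within a clade. The
hot change-counting loop is JIT-compiled with numba when available; the
public :func:`parsimony_score` is an independent vectorized Sankoff dynamic
program that also handles multifurcating trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import DICHOTOMOUS, ORDINAL4, CladelinkError, TraitMatrix

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except Exception:  # pragma: no cover
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]

__all__ = [
    "PhenoTree",
    "TreeSet",
    "parsimony_score",
    "ratchet_search",
    "spr_refine",
    "majority_consensus",
    "map_trait_changes",
    "TraitChange",
]

_FULL_MASK = np.uint8(0b1111)
_INF = np.float64(1e18)


# ---------------------------------------------------------------------------
# Public tree containers


class PhenoTree:
    """An unrooted tree over individuals (leaves labeled by uid).

    Internal nodes may be multifurcating (e.g. in consensus trees). Nodes are
    integers; ``labels`` maps leaf nodes to uid strings.
    """

    def __init__(self, adj: dict[int, list[int]], labels: dict[int, str]):
        self.adj = {u: list(vs) for u, vs in adj.items()}
        self.labels = dict(labels)
        for u, lab in self.labels.items():
            if len(self.adj.get(u, [])) > 1:
                raise CladelinkError(f"labeled node {lab} is not a leaf")

    # -- basic queries ------------------------------------------------------
    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def copy(self) -> "PhenoTree":
        return PhenoTree(self.adj, self.labels)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each given as the side not containing the
        lexicographically smallest leaf label."""
        if self.n_leaves < 4:
            return set()
        ref = min(self.labels.values())
        out: set[frozenset[str]] = set()
        seen_edges = set()
        for u in self.adj:
            for v in self.adj[u]:
                if (v, u) in seen_edges:
                    continue
                seen_edges.add((u, v))
                side = self._leaves_beyond(v, u)
                if ref in side:
                    side = self.leaf_labels - side
                if 2 <= len(side) <= self.n_leaves - 2:
                    out.add(frozenset(side))
        return out

    def _leaves_beyond(self, start: int, blocked: int) -> set[str]:
        out: set[str] = set()
        stack = [(start, blocked)]
        while stack:
            u, frm = stack.pop()
            if u in self.labels:
                out.add(self.labels[u])
            for w in self.adj[u]:
                if w != frm:
                    stack.append((w, u))
        return out

    # -- rooting / serialization -------------------------------------------
    def rooted_children(self, outgroup: str) -> tuple[int, dict[int, list[int]]]:
        """Root at the outgroup leaf's neighbor, drop the outgroup, and return
        ``(root, children)`` where ``children`` maps each node to its child
        nodes (empty for leaves)."""
        node = {lab: u for u, lab in self.labels.items()}[outgroup]
        if self.degree(node) != 1:
            raise CladelinkError(f"outgroup {outgroup} is not a leaf")
        root = self.adj[node][0]
        children: dict[int, list[int]] = {}
        stack = [(root, node)]
        while stack:
            u, frm = stack.pop()
            kids = [w for w in self.adj[u] if w != frm]
            children[u] = kids
            for w in kids:
                stack.append((w, u))
        return root, children

    def remove_leaf(self, label: str) -> "PhenoTree":
        """Return a copy without the given leaf, suppressing any resulting
        degree-2 node."""
        node = {lab: u for u, lab in self.labels.items()}[label]
        adj = {u: [v for v in vs if v != node] for u, vs in self.adj.items() if u != node}
        labels = {u: l for u, l in self.labels.items() if u != node}
        # suppress degree-2 unlabeled nodes
        changed = True
        while changed:
            changed = False
            for u in list(adj):
                if u not in labels and len(adj[u]) == 2:
                    a, b = adj[u]
                    adj[a] = [x if x != u else b for x in adj[a]]
                    adj[b] = [x if x != u else a for x in adj[b]]
                    del adj[u]
                    changed = True
                elif u not in labels and len(adj[u]) == 1 and len(adj) > 1:
                    a = adj[u][0]
                    adj[a] = [x for x in adj[a] if x != u]
                    del adj[u]
                    changed = True
        return PhenoTree(adj, labels)

    @staticmethod
    def _quote(lab: str) -> str:
        if any(c in lab for c in ":;,()[] '\t"):
            return "'" + lab.replace("'", "''") + "'"
        return lab

    def to_newick(self) -> str:
        if self.n_leaves == 1:
            (lab,) = self.labels.values()
            return f"{self._quote(lab)};"
        # root at an internal node (or at a leaf's neighbor)
        root = next((u for u in self.adj if u not in self.labels), None)
        if root is None:  # two-leaf tree
            labs = sorted(self.labels.values())
            return f"({self._quote(labs[0])},{self._quote(labs[1])});"

        def rec(u: int, frm: int | None) -> str:
            if u in self.labels:
                return self._quote(self.labels[u])
            parts = [rec(w, u) for w in self.adj[u] if w != frm]
            return "(" + ",".join(parts) + ")"

        return rec(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhenoTree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")
        adj: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        ids: dict = {}

        def nid(nd) -> int:
            if nd not in ids:
                ids[nd] = len(ids)
                adj[ids[nd]] = []
            return ids[nd]

        for edge in dt.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            a, b = nid(edge.tail_node), nid(edge.head_node)
            adj[a].append(b)
            adj[b].append(a)
        for leaf in dt.leaf_node_iter():
            labels[nid(leaf)] = leaf.taxon.label.replace(" ", "_")
        # suppress a degree-2 artificial root if present
        tree = cls(adj, labels)
        for u in list(tree.adj):
            if u not in tree.labels and tree.degree(u) == 2:
                a, b = tree.adj[u]
                tree.adj[a] = [x if x != u else b for x in tree.adj[a]]
                tree.adj[b] = [x if x != u else a for x in tree.adj[b]]
                del tree.adj[u]
        return tree


@dataclass
class TreeSet:
    """Equally parsimonious trees sharing one leaf set and one score."""

    trees: list[PhenoTree]
    score: float

    def __post_init__(self):
        if not self.trees:
            raise CladelinkError("empty TreeSet")
        ls = self.trees[0].leaf_labels
        if any(t.leaf_labels != ls for t in self.trees):
            raise CladelinkError("TreeSet trees have differing leaf sets")

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# Character data preparation


class CharacterData:
    """Leaf character states arranged for fast scoring.

    Splits characters into an unordered block (bitmask sets) and an ordered
    block (state intervals). Missing states become the full set / interval.
    """

    def __init__(self, matrix: TraitMatrix, uids: Sequence[str] | None = None,
                 ordered_ordinal: bool = True):
        if uids is None:
            uids = matrix.individual_ids
        missing = [u for u in uids if not matrix.is_scored(u)]
        if missing:
            raise CladelinkError(f"no trait row for {missing[0]}")
        self.uids = list(uids)
        sub = matrix.frame.loc[self.uids]
        states = np.where(np.isnan(sub.to_numpy()), -1, sub.to_numpy()).astype(np.int8)
        kinds = [matrix.trait_kinds[c] for c in sub.columns]
        self.trait_names = list(sub.columns)
        ordered = np.array([ordered_ordinal and k == ORDINAL4 for k in kinds])
        self.unord_traits = [n for n, o in zip(self.trait_names, ordered) if not o]
        self.ord_traits = [n for n, o in zip(self.trait_names, ordered) if o]
        su = states[:, ~ordered]
        so = states[:, ordered]
        self.masks = np.where(su < 0, _FULL_MASK,
                              np.left_shift(np.uint8(1), su.clip(min=0).astype(np.uint8))
                              ).astype(np.uint8)
        self.lo = np.where(so < 0, 0, so).astype(np.int8)
        self.hi = np.where(so < 0, 3, so).astype(np.int8)
        self.n_unord = self.masks.shape[1]
        self.n_ord = self.lo.shape[1]

    @property
    def n_leaves(self) -> int:
        return len(self.uids)


# ---------------------------------------------------------------------------
# Array-backed rooted-binary representation used during search


@_njit(cache=False)
def _count_kernel(post, left, right, masks, lo, hi, counts_u, counts_o):
    for i in range(post.shape[0]):
        v = post[i]
        l = left[v]
        r = right[v]
        for c in range(masks.shape[1]):
            m = masks[l, c] & masks[r, c]
            if m == 0:
                masks[v, c] = masks[l, c] | masks[r, c]
                counts_u[c] += 1
            else:
                masks[v, c] = m
        for c in range(lo.shape[1]):
            a = lo[l, c] if lo[l, c] > lo[r, c] else lo[r, c]
            b = hi[l, c] if hi[l, c] < hi[r, c] else hi[r, c]
            if a <= b:
                lo[v, c] = a
                hi[v, c] = b
            else:
                counts_o[c] += a - b
                lo[v, c] = b
                hi[v, c] = a


class _ATree:
    """Binary tree rooted on leaf 0's pendant edge, stored in flat arrays.

    Leaves are ``0..L-1``; internal nodes ``L..2L-3``; the root ``2L-2`` has
    leaf 0 as its left child. Equivalent to an unrooted binary tree on the
    leaves.
    """

    __slots__ = ("left", "right", "parent", "root", "L")

    def __init__(self, left, right, parent, root, L):
        self.left, self.right, self.parent = left, right, parent
        self.root, self.L = root, L

    def copy(self) -> "_ATree":
        return _ATree(self.left.copy(), self.right.copy(), self.parent.copy(),
                      self.root, self.L)

    @classmethod
    def from_adj(cls, adj: dict[int, list[int]], L: int) -> "_ATree":
        nn = 2 * L - 1
        left = np.full(nn, -1, np.int32)
        right = np.full(nn, -1, np.int32)
        parent = np.full(nn, -1, np.int32)
        root = nn - 1
        v0 = adj[0][0]
        left[root], right[root] = 0, v0
        parent[0] = root
        parent[v0] = root
        stack = [(v0, 0)]
        while stack:
            u, frm = stack.pop()
            kids = [w for w in adj[u] if w != frm]
            if kids:
                left[u], right[u] = kids
                parent[kids[0]] = u
                parent[kids[1]] = u
                stack.extend((w, u) for w in kids)
        return cls(left, right, parent, root, L)

    def to_adj(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}

        def _edge(a: int, b: int) -> None:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)

        for v in range(2 * self.L - 1):
            if v == self.root:
                continue
            p = int(self.parent[v])
            if p < 0 or p == self.root:
                continue
            _edge(p, v)
        # join the two children of the root directly
        _edge(int(self.left[self.root]), int(self.right[self.root]))
        return adj

    def postorder_internal(self) -> np.ndarray:
        out = np.empty(self.L - 1, np.int32)
        k = 0
        stack = [(self.root, False)]
        while stack:
            u, done = stack.pop()
            if u < self.L:
                continue
            if done:
                out[k] = u
                k += 1
                continue
            stack.append((u, True))
            stack.append((int(self.left[u]), False))
            stack.append((int(self.right[u]), False))
        return out[:k]

    def bipartition_key(self) -> frozenset[int]:
        """Canonical identity: leaf bitmasks below each non-root internal node."""
        masks = {}
        out = []
        for v in self.postorder_internal():
            l, r = int(self.left[v]), int(self.right[v])
            ml = masks.get(l, 1 << l if l < self.L else 0)
            mr = masks.get(r, 1 << r if r < self.L else 0)
            masks[v] = ml | mr
            if v != self.root:
                pc = bin(masks[v]).count("1")
                if 2 <= pc <= self.L - 2:
                    out.append(masks[v])
        return frozenset(out)


class _Scorer:
    """Shared buffers + kernel dispatch for one character data set."""

    def __init__(self, data: CharacterData):
        self.data = data
        L = data.n_leaves
        nn = 2 * L - 1
        self.masks = np.full((nn, data.n_unord), _FULL_MASK, np.uint8)
        self.masks[:L] = data.masks
        self.lo = np.zeros((nn, data.n_ord), np.int8)
        self.hi = np.full((nn, data.n_ord), 3, np.int8)
        self.lo[:L] = data.lo
        self.hi[:L] = data.hi
        self.counts_u = np.zeros(data.n_unord, np.int64)
        self.counts_o = np.zeros(data.n_ord, np.int64)

    def counts(self, tree: _ATree) -> tuple[np.ndarray, np.ndarray]:
        self.counts_u[:] = 0
        self.counts_o[:] = 0
        post = tree.postorder_internal()
        _count_kernel(post, tree.left, tree.right, self.masks, self.lo, self.hi,
                      self.counts_u, self.counts_o)
        return self.counts_u, self.counts_o

    def score(self, tree: _ATree, w_u: np.ndarray | None = None,
              w_o: np.ndarray | None = None) -> float:
        cu, co = self.counts(tree)
        if w_u is None:
            return float(cu.sum() + co.sum())
        return float(cu @ w_u + co @ w_o)


# ---------------------------------------------------------------------------
# Rearrangements


def _nni_moves(t: _ATree) -> list[tuple[int, int]]:
    moves = []
    for v in range(t.L, 2 * t.L - 2):
        p = int(t.parent[v])
        if p < 0 or p == t.root or t.left[v] < 0:
            continue
        moves.append((v, 0))
        moves.append((v, 1))
    return moves


def _apply_nni(t: _ATree, move: tuple[int, int]) -> _ATree:
    v, which = move
    out = t.copy()
    p = int(out.parent[v])
    s = int(out.right[p]) if int(out.left[p]) == v else int(out.left[p])
    c = int(out.left[v]) if which == 0 else int(out.right[v])
    # swap s and c
    if int(out.left[p]) == s:
        out.left[p] = c
    else:
        out.right[p] = c
    if int(out.left[v]) == c:
        out.left[v] = s
    else:
        out.right[v] = s
    out.parent[c] = p
    out.parent[s] = v
    return out


def _subtree_nodes(t: _ATree, v: int) -> set[int]:
    out = set()
    stack = [v]
    while stack:
        u = stack.pop()
        out.add(u)
        if u >= t.L and t.left[u] >= 0:
            stack.extend((int(t.left[u]), int(t.right[u])))
    return out


def _spr_moves(t: _ATree) -> list[tuple[int, int]]:
    moves = []
    for v in range(2 * t.L - 1):
        p = int(t.parent[v])
        if v == t.root or p < 0 or p == t.root or v == 0:
            continue
        sub = _subtree_nodes(t, v)
        s = int(t.right[p]) if int(t.left[p]) == v else int(t.left[p])
        for x in range(2 * t.L - 1):
            if x == t.root or x in sub or x == s or x == p:
                continue
            if int(t.parent[x]) < 0:
                continue
            moves.append((v, x))
    return moves


def _apply_spr(t: _ATree, move: tuple[int, int]) -> _ATree:
    v, x = move
    out = t.copy()
    p = int(out.parent[v])
    g = int(out.parent[p])
    s = int(out.right[p]) if int(out.left[p]) == v else int(out.left[p])
    # detach p, splice s up to g
    if int(out.left[g]) == p:
        out.left[g] = s
    else:
        out.right[g] = s
    out.parent[s] = g
    # re-insert p between x and its parent
    q = int(out.parent[x])
    if int(out.left[q]) == x:
        out.left[q] = p
    else:
        out.right[q] = p
    out.parent[p] = q
    out.left[p] = x
    out.right[p] = v
    out.parent[x] = p
    out.parent[v] = p
    return out


def _climb(t: _ATree, scorer: _Scorer, w_u, w_o, rng,
           moves_fn, apply_fn) -> tuple[_ATree, float]:
    """First-improvement hill climb until a local optimum."""
    cur = t
    cur_score = scorer.score(cur, w_u, w_o)
    improved = True
    while improved:
        improved = False
        moves = moves_fn(cur)
        order = rng.permutation(len(moves))
        for i in order:
            cand = apply_fn(cur, moves[int(i)])
            s = scorer.score(cand, w_u, w_o)
            if s < cur_score - 1e-12:
                cur, cur_score = cand, s
                improved = True
                break
    return cur, cur_score


# ---------------------------------------------------------------------------
# Construction helpers


def _stepwise_addition(data: CharacterData, scorer: _Scorer, rng) -> _ATree:
    """Greedy random-order stepwise addition start tree."""
    L = data.n_leaves
    order = [0] + [int(i) for i in rng.permutation(np.arange(1, L))]
    a, b, c = order[0], order[1], order[2]
    nid = L  # next internal id
    adj = {a: [nid], b: [nid], c: [nid], nid: [a, b, c]}
    nid += 1
    for leaf in order[3:]:
        best = None
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for (u, v) in edges:
            adj[u] = [x if x != v else nid for x in adj[u]]
            adj[v] = [x if x != u else nid for x in adj[v]]
            adj[nid] = [u, v, leaf]
            adj[leaf] = [nid]
            s = _partial_score(adj, data)
            if best is None or s < best[0]:
                best = (s, u, v)
            # undo
            adj[u] = [x if x != nid else v for x in adj[u]]
            adj[v] = [x if x != nid else u for x in adj[v]]
            del adj[nid]
            del adj[leaf]
        _, u, v = best
        adj[u] = [x if x != v else nid for x in adj[u]]
        adj[v] = [x if x != u else nid for x in adj[v]]
        adj[nid] = [u, v, leaf]
        adj[leaf] = [nid]
        nid += 1
    return _ATree.from_adj(adj, L)


def _partial_score(adj: dict[int, list[int]], data: CharacterData) -> float:
    """Score a partially built tree (subset of leaves) with fresh buffers."""
    leaves = sorted(u for u in adj if len(adj[u]) == 1)
    # relabel to 0..k-1 for a temporary _ATree
    relabel = {}
    for i, u in enumerate(leaves):
        relabel[u] = i
    nxt = len(leaves)
    for u in adj:
        if u not in relabel:
            relabel[u] = nxt
            nxt += 1
    adj2 = {relabel[u]: [relabel[v] for v in vs] for u, vs in adj.items()}
    t = _ATree.from_adj(adj2, len(leaves))
    masks = np.full((2 * len(leaves) - 1, data.n_unord), _FULL_MASK, np.uint8)
    lo = np.zeros((2 * len(leaves) - 1, data.n_ord), np.int8)
    hi = np.full((2 * len(leaves) - 1, data.n_ord), 3, np.int8)
    for u in leaves:
        masks[relabel[u]] = data.masks[u]
        lo[relabel[u]] = data.lo[u]
        hi[relabel[u]] = data.hi[u]
    cu = np.zeros(data.n_unord, np.int64)
    co = np.zeros(data.n_ord, np.int64)
    _count_kernel(t.postorder_internal(), t.left, t.right, masks, lo, hi, cu, co)
    return float(cu.sum() + co.sum())


# ---------------------------------------------------------------------------
# Public operations


def _group_duplicates(data_states: np.ndarray, uids: list[str]
                      ) -> tuple[list[int], dict[int, list[str]]]:
    """Representative row indices and representative -> member-uid groups."""
    seen: dict[bytes, int] = {}
    reps: list[int] = []
    groups: dict[int, list[str]] = {}
    for i, u in enumerate(uids):
        key = data_states[i].tobytes()
        if key in seen:
            groups[seen[key]].append(u)
        else:
            seen[key] = i
            reps.append(i)
            groups[i] = [u]
    return reps, groups


def _atree_to_phenotree(t: _ATree, rep_uids: list[str],
                        groups: dict[str, list[str]] | None = None) -> PhenoTree:
    adj = t.to_adj()
    labels = {i: rep_uids[i] for i in range(t.L)}
    if groups:
        # expand collapsed duplicate profiles into a polytomy at the leaf
        nxt = max(adj) + 1
        for i in range(t.L):
            members = groups.get(rep_uids[i], [rep_uids[i]])
            if len(members) == 1:
                continue
            hub = nxt
            nxt += 1
            nbr = adj[i][0]
            adj[nbr] = [x if x != i else hub for x in adj[nbr]]
            adj[hub] = [nbr, i]
            adj[i] = [hub]
            labels[i] = members[0]
            for lab in members[1:]:
                adj[hub].append(nxt)
                adj[nxt] = [hub]
                labels[nxt] = lab
                nxt += 1
    return PhenoTree(adj, labels)


def parsimony_score(tree: PhenoTree, matrix: TraitMatrix,
                    ordered_ordinal: bool = True) -> int:
    """Minimum total character changes of ``tree`` (Sankoff dynamic program).

    Handles multifurcations and missing states; dichotomous characters use
    unordered (Fitch) costs, four-state ordinal characters use ordered costs
    ``|i-j|`` unless ``ordered_ordinal`` is False.
    """
    labels = tree.labels
    missing = [lab for lab in tree.leaf_labels if not matrix.is_scored(lab)]
    if missing:
        raise CladelinkError(f"leaf {missing[0]} has no trait row")
    if tree.n_leaves <= 1:
        return 0
    sub = matrix.frame.loc[[labels[u] for u in sorted(labels)]]
    leaf_order = sorted(labels)
    states = np.where(np.isnan(sub.to_numpy()), -1, sub.to_numpy()).astype(int)
    kinds = [matrix.trait_kinds[c] for c in sub.columns]
    C = len(kinds)
    cost = np.zeros((C, 4, 4))
    for j, k in enumerate(kinds):
        for a in range(4):
            for b in range(4):
                if ordered_ordinal and k == ORDINAL4:
                    cost[j, a, b] = abs(a - b)
                else:
                    cost[j, a, b] = 0 if a == b else 1
    leaf_cost = {}
    for i, u in enumerate(leaf_order):
        vec = np.full((C, 4), _INF)
        s = states[i]
        vec[s < 0] = 0.0
        rows = np.where(s >= 0)[0]
        vec[rows, s[rows]] = 0.0
        leaf_cost[u] = vec

    root = next((u for u in tree.adj if u not in labels), leaf_order[0])
    total_cost = None
    # iterative postorder
    stack = [(root, None, False)]
    memo: dict[int, np.ndarray] = {}
    while stack:
        u, frm, done = stack.pop()
        kids = [w for w in tree.adj[u] if w != frm]
        if not done:
            stack.append((u, frm, True))
            for w in kids:
                stack.append((w, u, False))
            continue
        vec = leaf_cost[u].copy() if u in labels else np.zeros((C, 4))
        for w in kids:
            child = memo.pop(w)
            vec = vec + np.min(child[:, None, :] + cost, axis=2)
        memo[u] = vec
    total = memo[root].min(axis=1)
    return int(round(total.sum()))


def ratchet_search(matrix: TraitMatrix, n_iterations: int = 200,
                   reweight_fraction: float = 0.25, seed: int | None = 0,
                   max_trees: int = 1000, ordered_ordinal: bool = True,
                   collapse_duplicates: bool = True,
                   uids: Sequence[str] | None = None) -> TreeSet:
    """Heuristic parsimony ratchet search.

    Alternates hill climbs on a matrix with a random ``reweight_fraction`` of
    characters doubled in weight and on the original weights, keeping every
    distinct minimal-length tree encountered (up to ``max_trees``). Identical
    symptom profiles are collapsed to one leaf during search and re-expanded
    afterwards, which does not change the score. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    full = CharacterData(matrix, uids, ordered_ordinal)
    all_uids = full.uids
    states = np.hstack([full.masks.astype(np.int16),
                        full.lo.astype(np.int16), full.hi.astype(np.int16)])
    if collapse_duplicates:
        reps, grp_idx = _group_duplicates(states, all_uids)
    else:
        reps = list(range(len(all_uids)))
        grp_idx = {i: [all_uids[i]] for i in reps}
    rep_uids = [all_uids[i] for i in reps]
    groups = {all_uids[i]: grp_idx[i] for i in reps}
    data = CharacterData(matrix, rep_uids, ordered_ordinal)
    L = data.n_leaves

    if L < 4:
        tree = _trivial_tree(rep_uids, groups)
        return TreeSet([tree], parsimony_score(tree, matrix, ordered_ordinal))

    scorer = _Scorer(data)
    unit_u = np.ones(data.n_unord)
    unit_o = np.ones(data.n_ord)
    # SPR neighborhoods are affordable and far less prone to local optima on
    # small leaf sets; fall back to NNI rearrangements on large ones
    if L <= 16:
        moves_fn, apply_fn = _spr_moves, _apply_spr
    else:
        moves_fn, apply_fn = _nni_moves, _apply_nni
    start = _stepwise_addition(data, scorer, rng)
    cur, best_score = _climb(start, scorer, unit_u, unit_o, rng, moves_fn, apply_fn)
    best: dict[frozenset, _ATree] = {cur.bipartition_key(): cur}
    n_chars = data.n_unord + data.n_ord
    k = max(1, int(round(reweight_fraction * n_chars)))
    for _ in range(n_iterations):
        w_u = unit_u.copy()
        w_o = unit_o.copy()
        chosen = rng.choice(n_chars, size=k, replace=False)
        for c in chosen:
            if c < data.n_unord:
                w_u[c] = 2.0
            else:
                w_o[c - data.n_unord] = 2.0
        t1, _ = _climb(cur, scorer, w_u, w_o, rng, moves_fn, apply_fn)
        t2, s2 = _climb(t1, scorer, unit_u, unit_o, rng, moves_fn, apply_fn)
        if s2 < best_score - 1e-12:
            best_score = s2
            best = {t2.bipartition_key(): t2}
            cur = t2
        elif abs(s2 - best_score) <= 1e-12:
            if len(best) < max_trees:
                best.setdefault(t2.bipartition_key(), t2)
            cur = t2
        # else: keep current position (ratchet restarts from accepted tree)
    trees = [_atree_to_phenotree(t, rep_uids, groups)
             for _, t in sorted(best.items(), key=lambda kv: sorted(kv[0]))]
    return TreeSet(trees, best_score)


def _trivial_tree(rep_uids: list[str], groups: dict[str, list[str]]) -> PhenoTree:
    all_labels = [lab for u in rep_uids for lab in groups.get(u, [u])]
    if len(all_labels) == 1:
        return PhenoTree({0: []}, {0: all_labels[0]})
    if len(all_labels) == 2:
        return PhenoTree({0: [1], 1: [0]}, {0: all_labels[0], 1: all_labels[1]})
    hub = len(all_labels)
    adj = {hub: list(range(len(all_labels)))}
    labels = {}
    for i, lab in enumerate(all_labels):
        adj[i] = [hub]
        labels[i] = lab
    return PhenoTree(adj, labels)


def spr_refine(tree_set: TreeSet, matrix: TraitMatrix, seed: int | None = 0,
               max_trees: int = 1000, ordered_ordinal: bool = True) -> TreeSet:
    """SPR hill climbing from every input tree; never worsens the score.

    Intended for within-clade refinement: restrict ``matrix`` to the clade's
    members first.
    """
    rng = np.random.default_rng(seed)
    uids = sorted(tree_set.trees[0].leaf_labels)
    data = CharacterData(matrix, uids, ordered_ordinal)
    if data.n_leaves < 4:
        return tree_set
    scorer = _Scorer(data)
    unit_u = np.ones(data.n_unord)
    unit_o = np.ones(data.n_ord)
    pos = {u: i for i, u in enumerate(uids)}
    best_score = None
    best: dict[frozenset, _ATree] = {}
    for tree in tree_set.trees:
        at = _phenotree_to_atree(tree, pos)
        t, s = _climb(at, scorer, unit_u, unit_o, rng, _spr_moves, _apply_spr)
        if best_score is None or s < best_score - 1e-12:
            best_score = s
            best = {t.bipartition_key(): t}
        elif abs(s - best_score) <= 1e-12 and len(best) < max_trees:
            best.setdefault(t.bipartition_key(), t)
    trees = [_atree_to_phenotree(t, uids) for _, t in
             sorted(best.items(), key=lambda kv: sorted(kv[0]))]
    return TreeSet(trees, best_score)


def _phenotree_to_atree(tree: PhenoTree, pos: dict[str, int]) -> _ATree:
    """Convert (resolving any multifurcations arbitrarily) to array form."""
    L = len(pos)
    adj: dict[int, list[int]] = {}
    node_map: dict[int, int] = {}
    nxt = [L]

    def mid(u: int) -> int:
        if u not in node_map:
            if u in tree.labels:
                node_map[u] = pos[tree.labels[u]]
            else:
                node_map[u] = nxt[0]
                nxt[0] += 1
        return node_map[u]

    for u in tree.adj:
        adj[mid(u)] = []
    for u in tree.adj:
        for v in tree.adj[u]:
            adj[mid(u)].append(mid(v))
    # resolve multifurcations: any node with degree > 3 gets split
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            deg = len(adj[u])
            limit = 3
            if deg > limit:
                a, b = adj[u][0], adj[u][1]
                w = nxt[0]
                nxt[0] += 1
                adj[u] = [w] + adj[u][2:]
                adj[w] = [u, a, b]
                adj[a] = [x if x != u else w for x in adj[a]]
                adj[b] = [x if x != u else w for x in adj[b]]
                changed = True
    return _ATree.from_adj(adj, L)


def majority_consensus(tree_set: TreeSet, threshold: float = 0.51) -> PhenoTree:
    """Majority-rule consensus: exactly the splits in more than ``threshold``
    of the input trees, multifurcating where unresolved."""
    trees = tree_set.trees
    labels = sorted(trees[0].leaf_labels)
    n = len(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    keep = [bp for bp, c in counts.items() if c / n > threshold]
    return _tree_from_clades(labels, keep)


def _tree_from_clades(labels: list[str], clades: Iterable[frozenset[str]]) -> PhenoTree:
    L = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    adj: dict[int, list[int]] = {}
    node_labels: dict[int, str] = {}
    nxt = [L]
    root = nxt[0]
    nxt[0] += 1
    children: dict[int, list[int]] = {root: list(range(L))}
    parent: dict[int, int] = {i: root for i in range(L)}
    leafset: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(L)}
    leafset[root] = frozenset(labels)
    for clade in sorted(set(clades), key=lambda c: (-len(c), sorted(c))):
        # find deepest node containing the clade
        host = root
        descended = True
        while descended:
            descended = False
            for ch in children.get(host, []):
                if ch >= L and clade <= leafset[ch]:
                    host = ch
                    descended = True
                    break
        inside = [ch for ch in children[host] if leafset[ch] <= clade]
        if frozenset().union(*(leafset[ch] for ch in inside)) != clade:
            continue  # incompatible (cannot occur for strict-majority splits)
        node = nxt[0]
        nxt[0] += 1
        children[host] = [ch for ch in children[host] if ch not in inside] + [node]
        children[node] = inside
        leafset[node] = clade
        for ch in inside:
            parent[ch] = node
        parent[node] = host
    for u, chs in children.items():
        adj.setdefault(u, [])
        for ch in chs:
            adj[u].append(ch)
            adj.setdefault(ch, []).append(u)
    for i in range(L):
        node_labels[i] = labels[i]
    tree = PhenoTree(adj, node_labels)
    # suppress a degree-2 root
    if len(tree.adj[root]) == 2:
        a, b = tree.adj[root]
        tree.adj[a] = [x if x != root else b for x in tree.adj[a]]
        tree.adj[b] = [x if x != root else a for x in tree.adj[b]]
        del tree.adj[root]
    return tree


@dataclass(frozen=True)
class TraitChange:
    parent_node: int
    child_node: int
    trait: str
    direction: str  # "gain" | "loss"
    steps: int


def map_trait_changes(tree: PhenoTree, matrix: TraitMatrix,
                      ordered_ordinal: bool = True) -> list[TraitChange]:
    """One minimal-change assignment of states to internal nodes.

    Returns per-edge gains (state increase along the edge, away from the
    root) and losses; total steps equal :func:`parsimony_score`. Ties in the
    backtrace prefer keeping the parent state, then the smallest state.
    """
    if tree.n_leaves <= 1:
        return []
    labels = tree.labels
    leaf_order = sorted(labels)
    sub = matrix.frame.loc[[labels[u] for u in leaf_order]]
    states = np.where(np.isnan(sub.to_numpy()), -1, sub.to_numpy()).astype(int)
    kinds = [matrix.trait_kinds[c] for c in sub.columns]
    names = list(sub.columns)
    C = len(kinds)
    cost = np.zeros((C, 4, 4))
    for j, k in enumerate(kinds):
        for a in range(4):
            for b in range(4):
                cost[j, a, b] = abs(a - b) if (ordered_ordinal and k == ORDINAL4) \
                    else (0 if a == b else 1)
    leaf_cost = {}
    for i, u in enumerate(leaf_order):
        vec = np.full((C, 4), _INF)
        s = states[i]
        vec[s < 0] = 0.0
        rows = np.where(s >= 0)[0]
        vec[rows, s[rows]] = 0.0
        leaf_cost[u] = vec
    root = next((u for u in tree.adj if u not in labels), leaf_order[0])
    memo: dict[int, np.ndarray] = {}
    order: list[tuple[int, int | None]] = []
    stack = [(root, None, False)]
    while stack:
        u, frm, done = stack.pop()
        kids = [w for w in tree.adj[u] if w != frm]
        if not done:
            stack.append((u, frm, True))
            for w in kids:
                stack.append((w, u, False))
            continue
        order.append((u, frm))
        vec = leaf_cost[u].copy() if u in labels else np.zeros((C, 4))
        for w in kids:
            vec = vec + np.min(memo[w][:, None, :] + cost, axis=2)
        memo[u] = vec
    # backtrace (preorder)
    assign: dict[int, np.ndarray] = {root: memo[root].argmin(axis=1)}
    changes: list[TraitChange] = []
    pre = [(root, None)]
    seen = {root}
    while pre:
        u, frm = pre.pop()
        for w in tree.adj[u]:
            if w == frm or w in seen:
                continue
            seen.add(w)
            ps = assign[u]
            tot = memo[w] + cost[np.arange(C)[:, None], ps[:, None], np.arange(4)[None, :]]
            best = tot.min(axis=1)
            ws = np.empty(C, dtype=int)
            for j in range(C):
                cands = np.where(np.abs(tot[j] - best[j]) < 1e-9)[0]
                ws[j] = ps[j] if ps[j] in cands else cands.min()
            assign[w] = ws
            for j in range(C):
                if ws[j] != ps[j]:
                    d = int(ws[j] - ps[j])
                    changes.append(TraitChange(u, w, names[j],
                                               "gain" if d > 0 else "loss", abs(d)))
            pre.append((w, u))
    return changes
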