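"""Internal Fitch-parsimony engine on array-encoded binary trees.

State sets are uint8 bitmasks over (node, site): A=1, G=2, C=4, T=8;
anything ambiguous is 15 (any state, contributes no cost).  For unit-cost
parsimony the Sankoff cost vector of a subtree takes only two values
(m on the Fitch set, m+1 off it), so a subtree is fully summarised by
(set, m) per site.  Joining two summaries is therefore exact:

    join((S1, m1), (S2, m2)) = (S1 & S2, m1 + m2)        if S1 & S2 != 0
                               (S1 | S2, m1 + m2 + 1)    otherwise

which is what both the NNI rearrangement deltas and the stepwise-addition
insertion costs use.

The tree is rooted on the pendant edge of tip 0: the root has children
tip 0 and one internal node, so every internal edge of the unrooted tree
is a parent-child pair of internal rooted nodes.
"""

from __future__ import annotations

import numpy as np

#: bitmask encoding from the package base codes (A=0,G=1,C=2,T=3)
_MASK = np.array([1, 2, 4, 8], dtype=np.uint8)


def encode_bitmask(encoded: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, L) Fitch bitmasks; missing -> 15."""
    out = np.full(encoded.shape, 15, dtype=np.uint8)
    ok = encoded < 4
    out[ok] = _MASK[encoded[ok]]
    return out


class ParsimonyTree:
    """Mutable rooted-binary tree over ``n_tips`` tips with Fitch caches."""

    def __init__(self, n_tips: int, tip_masks: np.ndarray):
        if n_tips < 3:
            raise ValueError("need at least 3 tips")
        self.n_tips = n_tips
        self.L = tip_masks.shape[1]
        n_nodes = 2 * n_tips - 1
        self.left = np.full(n_nodes, -1, dtype=np.int32)
        self.right = np.full(n_nodes, -1, dtype=np.int32)
        self.parent = np.full(n_nodes, -1, dtype=np.int32)
        self.root = n_nodes - 1
        self.dset = np.zeros((n_nodes, self.L), dtype=np.uint8)
        self.dcost = np.zeros((n_nodes, self.L), dtype=np.int32)
        self.uset = np.zeros((n_nodes, self.L), dtype=np.uint8)
        self.ucost = np.zeros((n_nodes, self.L), dtype=np.int32)
        self.dset[:n_tips] = tip_masks

    # -- construction -----------------------------------------------------

    @classmethod
    def from_topology(cls, children: dict[int, tuple[int, int]], n_tips: int,
                      tip_masks: np.ndarray) -> "ParsimonyTree":
        """Build from an explicit internal-node -> (left, right) map whose
        root is node ``2*n_tips - 2``."""
        t = cls(n_tips, tip_masks)
        for node, (a, b) in children.items():
            t.left[node] = a
            t.right[node] = b
            t.parent[a] = node
            t.parent[b] = node
        t.refresh()
        return t

    def postorder(self) -> list[int]:
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if self.left[v] >= 0:
                stack.append(self.left[v])
                stack.append(self.right[v])
        return order[::-1]

    # -- Fitch passes ------------------------------------------------------

    @staticmethod
    def _join(s1, m1, s2, m2):
        inter = s1 & s2
        miss = inter == 0
        sset = np.where(miss, s1 | s2, inter)
        return sset, m1 + m2 + miss

    def refresh(self) -> None:
        """Recompute down- and up-pass caches; call after any topology edit."""
        order = self.postorder()
        for v in order:
            a = self.left[v]
            if a < 0:
                continue
            b = self.right[v]
            self.dset[v], self.dcost[v] = self._join(
                self.dset[a], self.dcost[a], self.dset[b], self.dcost[b]
            )
        # up pass (preorder); children of root see each other as context
        ra, rb = self.left[self.root], self.right[self.root]
        self.uset[ra], self.ucost[ra] = self.dset[rb], self.dcost[rb]
        self.uset[rb], self.ucost[rb] = self.dset[ra], self.dcost[ra]
        for v in order[::-1]:
            if v == self.root:
                continue
            for ch, sib in ((self.left[v], self.right[v]),
                            (self.right[v], self.left[v])):
                if ch < 0:
                    continue
                self.uset[ch], self.ucost[ch] = self._join(
                    self.uset[v], self.ucost[v], self.dset[sib], self.dcost[sib]
                )

    def score(self) -> int:
        ra, rb = self.left[self.root], self.right[self.root]
        _, m = self._join(self.dset[ra], self.dcost[ra],
                          self.dset[rb], self.dcost[rb])
        return int(m.sum())

    # -- NNI ---------------------------------------------------------------

    def nni_candidates(self) -> list[int]:
        """Internal nodes v whose edge (parent(v), v) is an internal edge."""
        out = []
        for v in range(self.n_tips, 2 * self.n_tips - 1):
            p = self.parent[v]
            if p >= 0 and p != self.root and self.left[v] >= 0:
                out.append(v)
        return out

    def nni_delta(self, v: int) -> tuple[int, int]:
        """Best score change (new - old) of the two NNIs at edge
        (parent(v), v), and which variant (1: swap right<->sibling,
        2: swap left<->sibling)."""
        p = self.parent[v]
        a, b = self.left[v], self.right[v]
        c = self.right[p] if self.left[p] == v else self.left[p]
        A = (self.dset[a], self.dcost[a])
        B = (self.dset[b], self.dcost[b])
        C = (self.dset[c], self.dcost[c])
        U = (self.uset[p], self.ucost[p])

        def total(x, y, z, w):
            s1, m1 = self._join(*x, *y)
            s2, m2 = self._join(*z, *w)
            _, m = self._join(s1, m1, s2, m2)
            return int(m.sum())

        cur = total(A, B, C, U)
        alt1 = total(A, C, B, U)
        alt2 = total(B, C, A, U)
        if alt1 <= alt2:
            return alt1 - cur, 1
        return alt2 - cur, 2

    def apply_nni(self, v: int, variant: int) -> None:
        p = self.parent[v]
        c_is_left = self.left[p] != v
        c = self.left[p] if c_is_left else self.right[p]
        if variant == 1:
            moved = self.right[v]
            self.right[v] = c
        else:
            moved = self.left[v]
            self.left[v] = c
        if c_is_left:
            self.left[p] = moved
        else:
            self.right[p] = moved
        self.parent[c] = v
        self.parent[moved] = p
        self.refresh()

    def hill_climb(self, max_moves: int = 100) -> int:
        """Greedy NNI: apply the single best improving move per sweep."""
        moves = 0
        while moves < max_moves:
            best_delta, best_v, best_var = 0, -1, 0
            for v in self.nni_candidates():
                delta, var = self.nni_delta(v)
                if delta < best_delta:
                    best_delta, best_v, best_var = delta, v, var
            if best_v < 0:
                break
            self.apply_nni(best_v, best_var)
            moves += 1
        return moves

    # -- edge lengths and export -------------------------------------------

    def fitch_edge_lengths(self) -> np.ndarray:
        """Mutation counts per edge under one deterministic minimal
        reconstruction (lowest-bit tie-break)."""
        def pick(mask):
            return mask & (~mask + 1)  # lowest set bit

        n_nodes = 2 * self.n_tips - 1
        states = np.zeros((n_nodes, self.L), dtype=np.uint8)
        ra, rb = self.left[self.root], self.right[self.root]
        rset, _ = self._join(self.dset[ra], self.dcost[ra],
                             self.dset[rb], self.dcost[rb])
        states[self.root] = pick(rset)
        lengths = np.zeros(n_nodes, dtype=np.int64)
        stack = [self.root]
        while stack:
            v = stack.pop()
            for ch in (self.left[v], self.right[v]):
                if ch < 0:
                    continue
                inherit = (states[v] & self.dset[ch]) != 0
                st = np.where(inherit, states[v], pick(self.dset[ch]))
                states[ch] = st
                lengths[ch] = int((st != states[v]).sum())
                stack.append(ch)
        return lengths

    def to_newick(self, labels: list[str], edge_lengths: np.ndarray | None = None) -> str:
        """Unrooted newick (root suppressed into a trifurcation-free shape:
        the artificial root keeps its two children; consumers may reroot)."""
        if edge_lengths is None:
            edge_lengths = self.fitch_edge_lengths()

        def rec(v):
            if self.left[v] < 0:
                return f"{labels[v]}:{edge_lengths[v]}"
            return (f"({rec(self.left[v])},{rec(self.right[v])})"
                    f":{edge_lengths[v]}")

        ra, rb = self.left[self.root], self.right[self.root]
        return f"({rec(ra)},{rec(rb)});"


def fitch_score_tree(children: dict[int, tuple[int, int]], n_tips: int,
                     tip_masks: np.ndarray) -> int:
    t = ParsimonyTree.from_topology(children, n_tips, tip_masks)
    return t.score()


def stepwise_addition(tip_masks: np.ndarray, order: np.ndarray) -> ParsimonyTree:
    """Greedy maximum-parsimony stepwise addition in the given taxon order.

    Exact insertion costs come from joining the new tip's state set with
    the (down, up) context of every edge.  Suitable for moderate taxon
    counts; the benchmark instead seeds hill-climbing with the NJ topology.
    """
    n_tips = tip_masks.shape[0]
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    order = list(order)
    root = 2 * n_tips - 2
    next_internal = n_tips
    children: dict[int, tuple[int, int]] = {}
    a, b, c = order[0], order[1], order[2]
    inner = next_internal
    next_internal += 1
    children[inner] = (b, c)
    root_children = [a, inner]

    def build_tree() -> ParsimonyTree:
        ch = dict(children)
        ch[root] = (root_children[0], root_children[1])
        return ParsimonyTree.from_topology(ch, n_tips, tip_masks)

    tree = build_tree()
    for x in order[3:]:
        xmask = tip_masks[x]
        best_v, best_cost = -1, None
        for v in range(root):
            if tree.parent[v] < 0:
                continue
            D = tree.dset[v]
            U = tree.uset[v]
            t_empty = ((D & U) == 0).astype(np.int32)
            cx = ((xmask & D) == 0).astype(np.int32) + ((xmask & U) == 0).astype(np.int32)
            cost = int(np.minimum(cx, 1 + t_empty).sum() - t_empty.sum())
            if best_cost is None or cost < best_cost:
                best_v, best_cost = v, cost
        p = tree.parent[best_v]
        new = next_internal
        next_internal += 1
        children[new] = (best_v, x)
        if p == root:
            root_children = [new if rc == best_v else rc for rc in root_children]
        else:
            pa, pb = children[p]
            children[p] = (new if pa == best_v else pa, new if pb == best_v else pb)
        tree = build_tree()
    return tree
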