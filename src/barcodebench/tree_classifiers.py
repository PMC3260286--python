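"""Tree-based identification: neighbor joining and parsimony.

Both methods build a single tree containing reference and query sequences
and assign each query from its position in that tree, following the
strict/liberal assessment of Ross et al.-style tree matching:

* liberal — if the query's sister group consists of references of a
  single species X, assign X;
* strict — additionally require the next-enclosing neighbourhood (the
  sister group of the clade formed by the query and its sister group) to
  be all X; i.e. the query must be nested within a mono-specific clade.

Queries are assessed one at a time: when several queries are placed in
the same tree, the other queries are ignored (logically pruned) while
walking the tree, so co-placed unknowns cannot make each other's
neighbourhoods look mixed.  Trees are midpoint-rooted before assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._fitch import ParsimonyTree, encode_bitmask, stepwise_addition
from .distances import DistanceMatrix, k2p_pairwise_matrix
from .records import UNCERTAIN, BarcodeSet, Identification, encode_sequence


@dataclass
class TreeSearchParams:
    """Heuristic settings for the parsimony search."""

    n_random_addition_starts: int = 1
    rearrangement: str = "NNI"
    max_iterations: int = 100
    start_from_nj: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_random_addition_starts < 1 or self.max_iterations < 1:
            raise ValueError("counts must be positive")
        if self.rearrangement != "NNI":
            raise ValueError("only NNI rearrangement is implemented")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def build_nj_tree(dm: DistanceMatrix, seed: int | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a seeded shuffle of the input order.

    The input order is randomly permuted (as in shuffling the rows of the
    distance matrix) so that tie-breaking does not depend on how the data
    happened to be sorted.  Undefined (NaN) entries are an error naming
    the offending pairs.
    """
    bad = dm.undefined_pairs()
    if bad:
        shown = ", ".join(f"{a}-{b}" for a, b in bad[:5])
        raise ValueError(
            f"distance matrix has {len(bad)} undefined entries (e.g. {shown})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dm.ids))
    ids = [dm.ids[i] for i in perm]
    d = dm.data[np.ix_(perm, perm)].astype(float).copy()
    newick = _nj_newick(d, ids)
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _nj_newick(d: np.ndarray, ids: list[str]) -> str:
    """Vectorised canonical NJ; returns an unrooted newick string."""
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        return f"({ids[0]}:{d[0, 1] / 2:.10g},{ids[1]}:{d[0, 1] / 2:.10g});"
    nodes = list(ids)  # newick fragment per active slot
    full = d.copy()
    # in-place agglomeration: merged cluster overwrites slot i, the last
    # active slot moves into j, so the working matrix is always the
    # leading (m, m) block
    while len(nodes) > 3:
        m = full.shape[0]
        active = full
        r = active.sum(axis=1)
        q = (m - 2) * active - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        dij = active[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = (active[i] + active[j] - dij) / 2
        active[i, :] = dnew
        active[:, i] = dnew
        active[i, i] = 0.0
        nodes[i] = merged
        last = m - 1
        if j != last:
            active[j, :] = active[last, :]
            active[:, j] = active[:, last]
            active[j, j] = 0.0
            nodes[j] = nodes[last]
        nodes.pop()
        full = active[:last, :last]
    active = full
    # final three-point resolution
    d01, d02, d12 = active[0, 1], active[0, 2], active[1, 2]
    l0 = (d01 + d02 - d12) / 2
    l1 = (d01 + d12 - d02) / 2
    l2 = (d02 + d12 - d01) / 2
    return (
        f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},{nodes[2]}:{l2:.10g});"
    )


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------


def fitch_length(tree: dendropy.Tree, sequences: dict[str, str]) -> int:
    """Parsimony score of ``tree`` for the given tip sequences.

    Internal nodes must be bifurcating; the seed node may have three
    children (the usual unrooted representation).
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    idx = {label: i for i, label in enumerate(leaves)}
    masks = encode_bitmask(
        np.vstack([encode_sequence(sequences[label]) for label in leaves])
    )
    # fold the tree into (set, cost) summaries bottom-up
    L = masks.shape[1]

    def join(x, y):
        s1, m1 = x
        s2, m2 = y
        inter = s1 & s2
        miss = inter == 0
        return np.where(miss, s1 | s2, inter), m1 + m2 + miss

    summaries: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    zero = np.zeros(L, dtype=np.int64)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            summaries[id(node)] = (masks[idx[node.taxon.label]], zero)
            continue
        ch = node.child_nodes()
        if len(ch) > 2 and node is not tree.seed_node:
            raise ValueError("internal multifurcations are not supported")
        if node is tree.seed_node and len(ch) > 2:
            # exact star join at the root: per-site cost over 4 states
            parts = [summaries[id(c)] for c in ch]
            base = sum(m for _, m in parts)
            per_state = np.zeros((4, L), dtype=np.int64)
            for s in range(4):
                bit = np.uint8(1 << s)
                for S, _ in parts:
                    per_state[s] += (S & bit) == 0
            return int((base + per_state.min(axis=0)).sum())
        acc = summaries[id(ch[0])]
        for c in ch[1:]:
            acc = join(acc, summaries[id(c)])
        summaries[id(node)] = acc
    _, m = summaries[id(tree.seed_node)]
    return int(m.sum())


def _collapse_duplicates(sequences: list[str], ids: list[str]):
    """Group identical sequences; returns (unique_seqs, rep_ids, groups)
    where groups[i] is the label-sorted list of member ids."""
    seen: dict[str, list[str]] = {}
    for sid, seq in sorted(zip(ids, sequences)):
        seen.setdefault(seq, []).append(sid)
    unique = sorted(seen, key=lambda s: seen[s][0])
    groups = [sorted(seen[s]) for s in unique]
    reps = [g[0] for g in groups]
    return unique, reps, groups


def parsimony_search(
    sequences: dict[str, str], params: TreeSearchParams | None = None
) -> dendropy.Tree:
    """Heuristic maximum-parsimony tree for the given sequences.

    Duplicate sequences are collapsed before the search and re-grafted
    afterwards as zero-length ladders resolved deterministically by label.
    The search is random stepwise addition (or the NJ topology when
    ``start_from_nj``) followed by greedy NNI hill-climbing on the Fitch
    score; one best-found tree is returned, ties broken first-found.
    Branch lengths are Fitch mutation counts under one deterministic
    minimal reconstruction (used downstream for midpoint rooting).
    """
    params = params or TreeSearchParams()
    ids = sorted(sequences)
    if len(ids) < 4:
        raise ValueError("need at least 4 sequences")
    seqs = [sequences[i] for i in ids]
    unique, reps, groups = _collapse_duplicates(seqs, ids)
    if len(unique) < 3:
        # essentially no signal; return a trivial ladder over all ids
        newick = _ladder_newick(ids)
        return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    enc = np.vstack([encode_sequence(s) for s in unique])
    masks = encode_bitmask(enc)
    rng = np.random.default_rng(params.seed)

    best_tree: ParsimonyTree | None = None
    best_score = None
    n_starts = 1 if params.start_from_nj else params.n_random_addition_starts
    for _ in range(n_starts):
        if params.start_from_nj:
            tree = _nj_start_tree(enc, masks)
        else:
            tree = stepwise_addition(masks, rng.permutation(len(unique)))
        tree.hill_climb(max_moves=params.max_iterations)
        score = tree.score()
        if best_score is None or score < best_score:
            best_tree, best_score = tree, score

    lengths = best_tree.fitch_edge_lengths()
    rep_labels = [_regraft_newick(groups[i]) for i in range(len(unique))]
    newick = best_tree.to_newick(rep_labels, lengths)
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _nj_start_tree(enc: np.ndarray, masks: np.ndarray) -> ParsimonyTree:
    """NJ topology (K2P distances, saturated pairs capped) as an NNI start."""
    d = k2p_pairwise_matrix(enc)
    if np.isnan(d).any():
        cap = np.nanmax(d) * 1.5 if np.isfinite(np.nanmax(d)) else 1.0
        d = np.nan_to_num(d, nan=cap)
    n = d.shape[0]
    newick = _nj_newick(d, [str(i) for i in range(n)])
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _dendropy_to_parsimony(t, n, masks)


def _dendropy_to_parsimony(tree: dendropy.Tree, n_tips: int,
                           masks: np.ndarray) -> ParsimonyTree:
    """Convert an (unrooted, possibly trifurcating-seed) dendropy tree whose
    tip labels are stringified indices into the array engine, rooted on the
    pendant edge of tip 0."""
    # reroot so that tip 0's edge is the root edge
    tip0 = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == "0":
            tip0 = leaf
            break
    tree.reroot_at_edge(tip0.edge, update_bipartitions=False)
    tree.suppress_unifurcations()
    children: dict[int, tuple[int, int]] = {}
    next_internal = [n_tips]

    def rec(node) -> int:
        if node.is_leaf():
            return int(node.taxon.label)
        ch = [rec(c) for c in node.child_nodes()]
        # resolve any multifurcation left-to-right
        while len(ch) > 2:
            idx = next_internal[0]
            next_internal[0] += 1
            children[idx] = (ch[0], ch[1])
            ch = [idx] + ch[2:]
        idx = next_internal[0]
        next_internal[0] += 1
        children[idx] = (ch[0], ch[1])
        return idx

    root_kids = tree.seed_node.child_nodes()
    kids = [rec(c) for c in root_kids]
    while len(kids) > 2:
        idx = next_internal[0]
        next_internal[0] += 1
        children[idx] = (kids[0], kids[1])
        kids = [idx] + kids[2:]
    root = 2 * n_tips - 2
    children[root] = (kids[0], kids[1])
    return ParsimonyTree.from_topology(children, n_tips, masks)


def _regraft_newick(group: list[str]) -> str:
    """Zero-length ladder over a duplicate group (labels already sorted)."""
    if len(group) == 1:
        return group[0]
    s = f"({group[0]}:0,{group[1]}:0)"
    for g in group[2:]:
        s = f"({s}:0,{g}:0)"
    return s


def _ladder_newick(ids: list[str]) -> str:
    s = f"({ids[0]}:0,{ids[1]}:0)"
    for i in ids[2:]:
        s = f"({s}:0,{i}:0)"
    return s + ";"


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


class _AssignmentIndex:
    """Per-tree cache for repeated query assignment."""

    def __init__(self, tree: dendropy.Tree, species_map: dict[str, str],
                 query_ids: set[str]):
        self.species_map = species_map
        self.query_ids = set(query_ids)
        self.leaf = {}
        self.parent = {}
        self.summary = {}  # id(node) -> (n_nonquery, species or "MIXED" or None)
        for node in tree.postorder_node_iter():
            if node.parent_node is not None:
                self.parent[id(node)] = node.parent_node
            if node.is_leaf():
                label = node.taxon.label
                self.leaf[label] = node
                if label in self.query_ids:
                    self.summary[id(node)] = (0, None)
                else:
                    self.summary[id(node)] = (1, species_map[label])
            else:
                n = 0
                sp = None
                mixed = False
                for ch in node.child_nodes():
                    cn, csp = self.summary[id(ch)]
                    n += cn
                    if cn == 0:
                        continue
                    if csp == "MIXED" or (sp is not None and csp != sp):
                        mixed = True
                    sp = sp or csp
                self.summary[id(node)] = (n, "MIXED" if mixed else sp)
        self.node_children = {
            id(node): node.child_nodes()
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        }

    def shells(self, query_id: str, max_shells: int = 2) -> list[str | None]:
        """Species summaries of the first ``max_shells`` non-empty
        neighbourhoods around ``query_id``, ignoring other queries.
        Each entry is a species label (pure) or "MIXED"."""
        node = self.leaf[query_id]
        out: list[str | None] = []
        while len(out) < max_shells and id(node) in self.parent:
            p = self.parent[id(node)]
            n = 0
            sp = None
            mixed = False
            for sib in self.node_children[id(p)]:
                if sib is node:
                    continue
                cn, csp = self.summary[id(sib)]
                n += cn
                if cn == 0:
                    continue
                if csp == "MIXED" or (sp is not None and csp != sp):
                    mixed = True
                sp = sp or csp
            if n > 0:
                out.append("MIXED" if mixed else sp)
            node = p
        return out


def assign_from_tree(
    tree: dendropy.Tree,
    query_id: str,
    species_map: dict[str, str],
    mode: str = "liberal",
    other_queries: set[str] | frozenset[str] = frozenset(),
    method: str = "tree",
    _index: _AssignmentIndex | None = None,
) -> Identification:
    """Assign one query from its placement in a (midpoint-rooted) tree.

    ``species_map`` labels the reference tips; tips in ``other_queries``
    (and the query itself) are ignored while collecting neighbourhoods.
    """
    if mode not in ("strict", "liberal"):
        raise ValueError("mode must be 'strict' or 'liberal'")
    idx = _index or _AssignmentIndex(
        tree, species_map, set(other_queries) | {query_id}
    )
    if query_id not in idx.leaf:
        raise KeyError(f"query {query_id!r} not in tree")
    shells = idx.shells(query_id, max_shells=2)
    assigned = UNCERTAIN
    if shells and shells[0] not in (None, "MIXED"):
        if mode == "liberal":
            assigned = shells[0]
        elif len(shells) > 1 and shells[1] == shells[0]:
            assigned = shells[0]
    return Identification(query_id, assigned, method, mode)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _TreeClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the two tree methods."""

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.reference_sequences_ = X
        self.reference_labels_ = y
        self.classes_ = np.unique(y)
        return self

    def _build_tree(self, all_seqs: dict[str, str]) -> dendropy.Tree:
        raise NotImplementedError

    def predict(self, X):
        ids = self.identify(X)
        return np.array([i.assigned for i in ids], dtype=object)

    def identify(self, X) -> list[Identification]:
        X = list(X)
        refs = self.reference_sequences_
        ref_ids = [f"r{i}" for i in range(len(refs))]
        q_ids = [f"q{i}" for i in range(len(X))]
        all_seqs = dict(zip(ref_ids, refs)) | dict(zip(q_ids, X))
        tree = self._build_tree(all_seqs)
        midpoint_root(tree)
        species_map = dict(zip(ref_ids, self.reference_labels_))
        index = _AssignmentIndex(tree, species_map, set(q_ids))
        out = []
        for q in q_ids:
            out.append(
                assign_from_tree(
                    tree, q, species_map, self.mode,
                    other_queries=set(q_ids) - {q},
                    method=self._method_name, _index=index,
                )
            )
        return out


class NeighborJoiningClassifier(_TreeClassifierBase):
    """NJ barcode matcher (K2P distances, seeded input-order shuffle)."""

    _method_name = "nj"

    def __init__(self, mode: str = "liberal", random_state: int | None = 0):
        self.mode = mode
        self.random_state = random_state

    def _build_tree(self, all_seqs: dict[str, str]) -> dendropy.Tree:
        ids = list(all_seqs)
        enc = np.vstack([encode_sequence(all_seqs[i]) for i in ids])
        d = k2p_pairwise_matrix(enc)
        dm = DistanceMatrix(ids, d)
        return build_nj_tree(dm, seed=self.random_state)


class ParsimonyClassifier(_TreeClassifierBase):
    """Maximum-parsimony barcode matcher (heuristic single best tree)."""

    _method_name = "parsimony"

    def __init__(self, mode: str = "liberal",
                 params: TreeSearchParams | None = None):
        self.mode = mode
        self.params = params

    def _build_tree(self, all_seqs: dict[str, str]) -> dendropy.Tree:
        return parsimony_search(all_seqs, self.params)
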