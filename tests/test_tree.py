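"""Tree-based matcher tests: NJ, Fitch, parsimony search, assignment."""

import itertools

import dendropy
import numpy as np
import pytest

import barcodebench as bb
from barcodebench.distances import DistanceMatrix
from barcodebench.records import UNCERTAIN
from barcodebench.tree_classifiers import (
    _AssignmentIndex,
    _nj_newick,
    midpoint_root,
)


def _random_additive(n, rng):
    """Random binary tree with positive lengths -> (path matrix, newick)."""
    active = list(range(n))
    parent, blen = {}, {}
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False), reverse=True)
        a, b = active[i], active[j]
        active.pop(i)
        active.pop(j)
        parent[a], parent[b] = nxt, nxt
        blen[a] = rng.uniform(0.5, 3)
        blen[b] = rng.uniform(0.5, 3)
        active.append(nxt)
        nxt += 1

    def path(x):
        out, dist = {}, 0.0
        while x in parent:
            dist += blen[x]
            x = parent[x]
            out[x] = dist
        return out

    d = np.zeros((n, n))
    for i in range(n):
        pi = path(i)
        for j in range(i + 1, n):
            pj = path(j)
            d[i, j] = d[j, i] = min(
                pi[a] + pj[a] for a in pi if a in pj
            )
    return d


def _rf(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        nwk = _nj_newick(d, ["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        # three-point equations: la+lb=3, la+lc=5, lb+lc=6
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(4.0)

    def test_additive_four_taxon_exact_recovery(self):
        # ((A:2,B:3):1,(C:4,D:5)) pairwise distances
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        nwk = _nj_newick(d, list("ABCD"))
        assert _rf(nwk, "((A:2,B:3):1,C:4,D:5);") == 0
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(4), 2):
            got = pdm.distance(taxa["ABCD"[i]], taxa["ABCD"[j]])
            assert got == pytest.approx(d[i, j])

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_nj_is_exact_on_random_additive_matrices(self, n):
        rng = np.random.default_rng(n)
        for trial in range(10):
            d = _random_additive(n, rng)
            ids = [f"t{i}" for i in range(n)]
            nwk1 = _nj_newick(d.copy(), ids)
            # additive distances must be reproduced exactly
            tree = dendropy.Tree.get(data=nwk1, schema="newick")
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, j in itertools.combinations(range(n), 2):
                got = pdm.distance(taxa[ids[i]], taxa[ids[j]])
                assert got == pytest.approx(d[i, j], rel=1e-9)

    def test_seed_shuffle_does_not_change_tiefree_topology(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            d = _random_additive(6, rng)
            ids = [f"t{i}" for i in range(6)]
            dm = DistanceMatrix(ids, d)
            t1 = bb.build_nj_tree(dm, seed=1).as_string(schema="newick")
            t2 = bb.build_nj_tree(dm, seed=99).as_string(schema="newick")
            assert _rf(t1, t2) == 0

    def test_undefined_entries_error_names_pairs(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        dm = DistanceMatrix(["a", "b"], d)
        with pytest.raises(ValueError, match="a-b"):
            bb.build_nj_tree(dm)


class TestFitchLength:
    def _tree(self, nwk):
        return dendropy.Tree.get(data=nwk, schema="newick")

    def test_identical_sequences_score_zero(self):
        tree = self._tree("((a,b),(c,d));")
        seqs = {k: "ACGT" for k in "abcd"}
        assert bb.fitch_length(tree, seqs) == 0

    def test_single_informative_column(self):
        tree = self._tree("((a1,a2),(c1,c2));")
        seqs = {"a1": "A", "a2": "A", "c1": "C", "c2": "C"}
        assert bb.fitch_length(tree, seqs) == 1

    def test_random_cases_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            labels = [f"t{i}" for i in range(6)]
            frags = labels[:]
            while len(frags) > 1:
                i, j = sorted(rng.choice(len(frags), 2, replace=False), reverse=True)
                a, b = frags.pop(i), frags.pop(j)
                frags.append(f"({a},{b})")
            tree = self._tree(frags[0] + ";")
            seqs = {
                t: "".join(rng.choice(list("ACGT"), 5)) for t in labels
            }
            got = bb.fitch_length(tree, seqs)
            expect = _exhaustive_parsimony(tree, seqs)
            assert got == expect


def _exhaustive_parsimony(tree, seqs):
    """Brute-force minimal-change count over all ancestral assignments."""
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    L = len(next(iter(seqs.values())))
    total = 0
    for site in range(L):
        best = 10**9
        for assign in itertools.product("ACGT", repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assign)}
            for leaf in tree.leaf_node_iter():
                state[id(leaf)] = seqs[leaf.taxon.label][site]
            cost = 0
            for node in internals:
                for ch in node.child_nodes():
                    cost += state[id(node)] != state[id(ch)]
            best = min(best, cost)
        total += best
    return total


class TestParsimonySearch:
    def test_recovers_strong_signal_topology(self):
        """An alignment simulated on a known 8-tip tree with low noise is
        reconstructed exactly."""
        st = bb.simulate_yule_tree(8, 1e6, seed=31)
        gt = bb.simulate_gene_tree(
            st, bb.CoalescentParams(ne=100, samples_per_species=2), seed=32
        )
        bs = bb.simulate_sequences(gt, bb.SubstitutionModel(length=2000), seed=33)
        seqs = dict(zip(bs.ids(), bs.sequences()))
        tree = bb.parsimony_search(seqs, bb.TreeSearchParams(seed=0))
        # with Ne=100 every species is a clean cherry: per-species pairs
        # must be monophyletic in the inferred tree
        mono = bb.species_monophyly(tree, dict(zip(bs.ids(), bs.labels())))
        assert all(mono.values())

    def test_all_identical_alignment_scores_zero(self):
        seqs = {f"t{i}": "AAAA" for i in range(5)}
        tree = bb.parsimony_search(seqs, bb.TreeSearchParams(seed=0))
        assert bb.fitch_length(tree, seqs) == 0
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(seqs)

    def test_search_not_worse_than_nj_topology(self, small_replicate):
        bs = small_replicate.barcodes
        sub = bs.table.head(20)
        seqs = dict(zip(sub["individual_id"], sub["sequence"]))
        par_tree = bb.parsimony_search(seqs, bb.TreeSearchParams(seed=1))
        dm = bb.distance_matrix(bb.BarcodeSet(sub))
        nj_tree = bb.build_nj_tree(dm, seed=1)
        assert bb.fitch_length(par_tree, seqs) <= bb.fitch_length(nj_tree, seqs)


class TestAssignment:
    def _index(self, nwk, species_map, queries):
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        return tree, species_map, queries

    def test_fully_nested_query_assigned_in_both_modes(self):
        tree = dendropy.Tree.get(data="(((q:1,x1:1):1,x2:1):1,y1:3);", schema="newick")
        smap = {"x1": "X", "x2": "X", "y1": "Y"}
        for mode in ("strict", "liberal"):
            ident = bb.assign_from_tree(tree, "q", smap, mode=mode)
            assert ident.assigned == "X", mode

    def test_sister_to_cluster_liberal_only(self):
        tree = dendropy.Tree.get(data="((q:1,(x1:1,x2:1):1):1,y1:3);", schema="newick")
        smap = {"x1": "X", "x2": "X", "y1": "Y"}
        assert bb.assign_from_tree(tree, "q", smap, mode="liberal").assigned == "X"
        assert bb.assign_from_tree(tree, "q", smap, mode="strict").assigned == UNCERTAIN

    def test_mixed_sister_group_is_uncertain(self):
        tree = dendropy.Tree.get(data="((q:1,(x1:1,y2:1):1):1,y1:3);", schema="newick")
        smap = {"x1": "X", "y2": "Y", "y1": "Y"}
        for mode in ("strict", "liberal"):
            assert bb.assign_from_tree(tree, "q", smap, mode=mode).assigned == UNCERTAIN

    def test_other_queries_are_pruned_from_neighbourhoods(self):
        # q2 sits between q1 and its conspecific references: ignoring q2,
        # q1 is still sister to the x cluster
        tree = dendropy.Tree.get(
            data="(((q1:1,q2:1):1,(x1:1,x2:1):1):1,y1:3);", schema="newick"
        )
        smap = {"x1": "X", "x2": "X", "y1": "Y"}
        ident = bb.assign_from_tree(
            tree, "q1", smap, mode="liberal", other_queries={"q2"}
        )
        assert ident.assigned == "X"

    def test_query_missing_from_tree_errors(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:1);", schema="newick")
        with pytest.raises(KeyError):
            bb.assign_from_tree(tree, "zz", {"a": "A", "b": "B", "c": "C"})

    def test_liberal_success_dominates_strict(self, small_replicate):
        """Strict assignments are a subset of liberal ones: on any dataset
        liberal success >= strict success for both tree methods."""
        bs = small_replicate.barcodes
        refs, queries = bs.references, bs.queries
        for cls in (bb.NeighborJoiningClassifier, bb.ParsimonyClassifier):
            preds = {}
            for mode in ("liberal", "strict"):
                clf = cls(mode=mode).fit(refs.sequences(), refs.labels())
                preds[mode] = clf.predict(queries.sequences())
            truth = queries.labels()
            lib_ok = preds["liberal"] == truth
            strict_ok = preds["strict"] == truth
            assert strict_ok.sum() <= lib_ok.sum()
            # every strict assignment (non-UNCERTAIN) matches liberal's
            decided = preds["strict"] != UNCERTAIN
            assert (preds["strict"][decided] == preds["liberal"][decided]).all()
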