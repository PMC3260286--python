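"""Simulator tests: Yule sampler, coalescent, branch noise, HKY+Gamma."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import ks_2samp, truncnorm

import barcodebench as bb
from barcodebench.simulate import AGE_OLD, AGE_RECENT, GeneTree


# ---------------------------------------------------------------------------
# Yule species tree
# ---------------------------------------------------------------------------


def _forward_yule_heights(n_species, rng):
    """Independent forward-time birth-process oracle: returns the ranked
    internal node ages (rescaled to depth 1) of one simulated tree."""
    t = 0.0
    k = 1
    split_times = []
    while k < n_species:
        t += rng.exponential(1.0 / k)
        split_times.append(t)
        k += 1
    t_obs = t + rng.exponential(1.0 / n_species)
    root = split_times[0]
    ages = [(t_obs - s) / (t_obs - root) for s in split_times]
    return sorted(ages)


def test_two_species_tree_is_a_cherry():
    st = bb.simulate_yule_tree(2, 1e6, seed=0)
    assert sorted(st.table["species"]) == ["sp01", "sp02"]
    assert np.allclose(st.table["divergence_time"], 1e6)
    assert sorted(st.table["age_class"]) == [AGE_OLD, AGE_RECENT]


def test_fifty_species_split_into_equal_age_groups():
    st = bb.simulate_yule_tree(50, 1e6, seed=3)
    counts = st.table["age_class"].value_counts()
    assert counts[AGE_RECENT] == 25 and counts[AGE_OLD] == 25
    # recent species are the younger half by divergence time
    recent_max = st.table.loc[st.table.age_class == AGE_RECENT, "divergence_time"].max()
    old_min = st.table.loc[st.table.age_class == AGE_OLD, "divergence_time"].min()
    assert recent_max <= old_min


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        bb.simulate_yule_tree(1, 1e6)
    with pytest.raises(ValueError):
        bb.simulate_yule_tree(5, 0.0)


def test_yule_node_heights_match_forward_process_oracle():
    """Ranked internal node heights over many seeds agree with an
    independent forward birth-process simulation (KS test)."""
    n = 4
    mine = []
    for seed in range(1000):
        st = bb.simulate_yule_tree(n, 1.0, seed=seed)
        ages = sorted(
            node.distance_from_tip()
            for node in st.tree.preorder_internal_node_iter()
        )
        mine.append(ages)
    rng = np.random.default_rng(123456)
    oracle = [_forward_yule_heights(n, rng) for _ in range(1000)]
    mine = np.array(mine)
    oracle = np.array(oracle)
    # the deepest rank is the root, deterministically at the configured
    # depth (checked by the ultrametricity test); compare the others
    for rank in range(n - 2):
        p = ks_2samp(mine[:, rank], oracle[:, rank]).pvalue
        assert p > 0.01, f"rank {rank} heights diverge from Yule oracle (p={p})"


def test_ultrametric_invariant_enforced():
    st = bb.simulate_yule_tree(12, 1e6, seed=5)
    depths = [leaf.distance_from_root() for leaf in st.tree.leaf_node_iter()]
    assert np.allclose(depths, 1e6, rtol=1e-9)


# ---------------------------------------------------------------------------
# coalescent gene trees
# ---------------------------------------------------------------------------


def _two_species_tree(depth=1e6):
    nwk = f"(sp01:{depth},sp02:{depth});"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    return bb.SpeciesTree(tree, depth)


def test_within_species_tmrca_is_exponential_with_mean_ne():
    """Two samples from one species, Ne=1000: pairwise TMRCA has mean
    ~1000 generations (closed-form exponential oracle, 5000 reps)."""
    st = _two_species_tree()
    cp = bb.CoalescentParams(ne=1000, samples_per_species=2, ploidy_factor=1)
    tmrcas = []
    for seed in range(5000):
        gt = bb.simulate_gene_tree(st, cp, seed=seed)
        pdm = gt.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in gt.tree.taxon_namespace}
        d = pdm.distance(taxa["sp01_01"], taxa["sp01_02"])
        tmrcas.append(d / 2.0)
    mean = np.mean(tmrcas)
    # conditional on coalescing before the 1e6-generation species depth,
    # which happens with probability 1 - exp(-1000) ~ 1
    assert abs(mean - 1000) / 1000 < 0.05


def test_cross_species_tmrca_never_predates_divergence():
    st = _two_species_tree(depth=1e6)
    cp = bb.CoalescentParams(ne=1000, samples_per_species=2)
    for seed in range(200):
        gt = bb.simulate_gene_tree(st, cp, seed=seed)
        pdm = gt.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in gt.tree.taxon_namespace}
        d = pdm.distance(taxa["sp01_01"], taxa["sp02_01"])
        assert d / 2.0 >= 1e6 - 1e-6


def test_larger_ne_lowers_gene_tree_monophyly():
    """Species monophyly in the coalescent gene tree is rarer under
    Ne=50000 than Ne=1000 (paired over 50 seeds)."""
    st = bb.simulate_yule_tree(50, 1e6, seed=42)
    fracs = {}
    for ne in (1000, 50000):
        cp = bb.CoalescentParams(ne=ne, samples_per_species=4)
        vals = []
        for seed in range(50):
            gt = bb.simulate_gene_tree(st, cp, seed=seed)
            mono = bb.species_monophyly(gt.tree, gt.species_map)
            vals.append(np.mean(list(mono.values())))
        fracs[ne] = np.mean(vals)
    assert fracs[50000] < fracs[1000]


# ---------------------------------------------------------------------------
# branch noise
# ---------------------------------------------------------------------------


def test_zero_noise_is_identity():
    st = _two_species_tree()
    gt = bb.simulate_gene_tree(st, bb.CoalescentParams(ne=1000, samples_per_species=3), seed=1)
    noisy = bb.add_branch_noise(gt, bb.NoiseParams(0.0), seed=2)
    for e1, e2 in zip(gt.tree.preorder_edge_iter(), noisy.tree.preorder_edge_iter()):
        assert e1.length == e2.length


def test_noise_moments_match_truncated_normal_oracle():
    """b=1000, factor 0.7: sample mean/sd of redrawn-if-negative noise
    match the truncated-normal moments computed numerically."""
    b, f = 1000.0, 0.7
    n_tips = 20000
    star = "(" + ",".join(f"t{i}:{b}" for i in range(n_tips)) + ");"
    draws = []
    for seed in (1, 2, 3, 4, 5):
        tree = dendropy.Tree.get(data=star, schema="newick")
        gt = GeneTree(tree, {f"t{i}": "sp01" for i in range(n_tips)})
        noisy = bb.add_branch_noise(gt, bb.NoiseParams(f), seed=seed)
        draws.extend(leaf.edge.length for leaf in noisy.tree.leaf_node_iter())
    draws = np.array(draws)
    a_trunc = (0 - b) / (f * b)  # truncation at zero, in sd units
    oracle = truncnorm(a_trunc, np.inf, loc=b, scale=f * b)
    assert draws.mean() > b  # truncation biases the mean upward
    assert abs(draws.mean() - oracle.mean()) / oracle.mean() < 0.01
    assert abs(draws.std() - oracle.std()) / oracle.std() < 0.02


def test_noise_breaks_ultrametricity():
    st = bb.simulate_yule_tree(5, 1e6, seed=9)
    gt = bb.simulate_gene_tree(st, bb.CoalescentParams(ne=1000, samples_per_species=4), seed=9)
    noisy = bb.add_branch_noise(gt, bb.NoiseParams(0.7), seed=10)
    depths = [leaf.distance_from_root() for leaf in noisy.tree.leaf_node_iter()]
    assert np.std(depths) / np.mean(depths) > 1e-3


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def _two_tip_gene_tree(branch):
    tree = dendropy.Tree.get(data=f"(a:{branch},b:{branch});", schema="newick")
    return GeneTree(tree, {"a": "sp01", "b": "sp02"})


def test_zero_length_branches_give_identical_sequences():
    gt = _two_tip_gene_tree(0.0)
    bs = bb.simulate_sequences(gt, bb.SubstitutionModel(length=500), seed=0)
    seqs = bs.sequences()
    assert seqs[0] == seqs[1]


def test_transition_transversion_ratio_matches_expm_oracle():
    """Two tips at 0.2 expected subs/site total: observed ts:tv count
    ratio matches matrix exponentiation of the HKY rate matrix (+-3%)."""
    model = bb.SubstitutionModel(length=100_000, n_categories=1, rate_scale=1.0)
    gt = _two_tip_gene_tree(0.1)  # 0.1 per branch, 0.2 on the path
    bs = bb.simulate_sequences(gt, model, seed=7)
    a, b = (bb.records.encode_sequence(s) for s in bs.sequences())
    diff = a != b
    transition = diff & ((a >> 1) == (b >> 1))
    obs_ratio = transition.sum() / (diff.sum() - transition.sum())

    q = model.rate_matrix()
    pi = model.stationary()
    p = expm(q * 0.2)
    joint = pi[:, None] * p
    is_transition = np.zeros((4, 4), bool)
    for i in range(4):
        for j in range(4):
            if i != j and (i < 2) == (j < 2):
                is_transition[i, j] = True
    off = ~np.eye(4, dtype=bool)
    exp_ratio = joint[is_transition].sum() / joint[off & ~is_transition].sum()
    assert abs(obs_ratio - exp_ratio) / exp_ratio < 0.03


def test_base_composition_matches_stationary_frequencies():
    # sequences within one replicate share a root draw, so composition is
    # pooled over many independent replicates to beat that correlation
    st = bb.simulate_yule_tree(5, 1e6, seed=2)
    gt = bb.simulate_gene_tree(st, bb.CoalescentParams(ne=1000, samples_per_species=4), seed=3)
    counts = np.zeros(4)
    total = 0
    for seed in range(30):
        bs = bb.simulate_sequences(gt, bb.SubstitutionModel(length=650), seed=seed)
        enc = bs.encoded()
        for c in range(4):
            counts[c] += (enc == c).sum()
        total += enc.size
    assert total >= 1e5
    # internal codes: A=0,G=1,C=2,T=3; stated frequencies are A,C,G,T
    freqs = [counts[c] / total for c in (0, 2, 1, 3)]
    assert np.allclose(freqs, (0.30, 0.15, 0.10, 0.45), atol=0.01)


# ---------------------------------------------------------------------------
# reference/query split
# ---------------------------------------------------------------------------


def test_split_roles_sixteen_four(small_replicate):
    table = small_replicate.barcodes.table
    per_species = table.groupby("species")["role"].value_counts().unstack()
    assert (per_species["reference"] == 6).all()
    assert (per_species["query"] == 2).all()


def test_split_with_zero_queries():
    gt = _two_tip_gene_tree(10.0)
    bs = bb.simulate_sequences(gt, bb.SubstitutionModel(length=50), seed=0)
    out = bb.split_reference_query(bs, n_ref=1, n_query=0, seed=1)
    assert (out.table["role"] == "reference").all()
    assert len(out.queries) == 0


def test_split_wrong_count_errors():
    gt = _two_tip_gene_tree(10.0)
    bs = bb.simulate_sequences(gt, bb.SubstitutionModel(length=50), seed=0)
    with pytest.raises(ValueError):
        bb.split_reference_query(bs, n_ref=3, n_query=2, seed=1)


def test_split_is_deterministic_per_seed():
    st = bb.simulate_yule_tree(4, 1e6, seed=0)
    gt = bb.simulate_gene_tree(st, bb.CoalescentParams(ne=1000, samples_per_species=5), seed=1)
    bs = bb.simulate_sequences(gt, bb.SubstitutionModel(length=60), seed=2)
    r1 = bb.split_reference_query(bs, 4, 1, seed=77).table["role"].tolist()
    r2 = bb.split_reference_query(bs, 4, 1, seed=77).table["role"].tolist()
    r3 = bb.split_reference_query(bs, 4, 1, seed=78).table["role"].tolist()
    assert r1 == r2
    assert r1 != r3 or True  # different seed may coincide; only equality is guaranteed


def test_within_species_distance_increases_with_ne():
    """Mean within-species K2P distance grows monotonically in Ne
    (averaged over 30 replicates) — the lineage-sorting mechanism that
    erodes the barcode gap."""
    st = bb.simulate_yule_tree(8, 1e6, seed=21)
    model = bb.SubstitutionModel(length=300)
    means = []
    for ne in (1000, 10000, 50000):
        cp = bb.CoalescentParams(ne=ne, samples_per_species=4)
        vals = []
        for rep in range(30):
            gt = bb.simulate_gene_tree(st, cp, seed=1000 + rep)
            bs = bb.simulate_sequences(gt, model, seed=2000 + rep)
            dm = bb.distance_matrix(bs)
            labels = bs.labels()
            for sp in set(labels):
                mask = labels == sp
                sub = dm.data[np.ix_(mask, mask)]
                vals.append(np.nanmean(sub[np.triu_indices_from(sub, k=1)]))
        means.append(np.nanmean(vals))
    assert means[0] < means[1] < means[2]
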