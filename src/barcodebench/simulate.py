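"""Synthetic barcode data generator.

The generator reproduces the statistical structure assumed by the benchmark:

1. an ultrametric Yule (pure-birth) species tree for ``n_species`` species,
   rescaled to a fixed depth in generations;
2. multispecies-coalescent gene trees simulated within that species tree
   (msprime is the coalescent engine), with ``samples_per_species``
   individuals per species;
3. branch-length noise mimicking mutation-rate heterogeneity among
   lineages (normal, sd proportional to branch length, truncated at zero);
4. HKY+Gamma sequence simulation along the noisy gene tree;
5. a per-species split of the individuals into reference and query roles.

Species are classed as ``recent`` or ``old`` by the rank of their
divergence time (the length of their terminal species-tree branch): the
younger half is ``recent``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import msprime
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .records import ROLE_QUERY, ROLE_REFERENCE, BarcodeSet, decode_sequence

AGE_RECENT = "recent"
AGE_OLD = "old"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class CoalescentParams:
    """Within-species coalescent parameters.

    ``ne`` is the effective population size in individuals; the pairwise
    coalescence rate is ``1 / (ploidy_factor * ne)`` per generation.  The
    source study does not state whether Ne was treated as haploid or
    diploid; the default ``ploidy_factor=1`` uses the haploid convention,
    which only rescales (not reorders) lineage-sorting depth.
    """

    ne: float = 10_000.0
    samples_per_species: int = 20
    ploidy_factor: int = 1

    def __post_init__(self) -> None:
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if self.samples_per_species < 2:
            raise ValueError("samples_per_species must be >= 2")
        if self.ploidy_factor not in (1, 2):
            raise ValueError("ploidy_factor must be 1 or 2")


@dataclass
class NoiseParams:
    """Branch-length noise: b -> Normal(b, noise_factor * b), truncated.

    Negative draws are rejected and redrawn (up to ``max_redraws``; after
    that the branch length is set to 0).  ``noise_factor`` is interpreted
    as a standard-deviation multiplier: a variance of ``0.7 b^2``-squared
    scale would make the noise negligible on long branches and defeat its
    purpose of mimicking rate heterogeneity.
    """

    noise_factor: float = 0.7
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be >= 0")


@dataclass
class SubstitutionModel:
    """HKY substitution model with discrete-gamma rate variation.

    ``rate_scale`` converts branch lengths in generations into expected
    substitutions per site (substitutions/site/generation).  The default
    5e-8 makes the deepest splits of a 1e6-generation tree diverge by
    ~10% expected substitutions, comparable to empirical COI barcodes.
    """

    kappa: float = 8.3
    freqs: tuple[float, float, float, float] = (0.30, 0.15, 0.10, 0.45)  # A,C,G,T
    gamma_shape: float = 0.2
    n_categories: int = 4
    length: int = 650
    rate_scale: float = 5e-8

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if min(self.kappa, self.gamma_shape, self.rate_scale) <= 0:
            raise ValueError("kappa, gamma_shape and rate_scale must be > 0")
        if self.length <= 0 or self.n_categories <= 0:
            raise ValueError("length and n_categories must be > 0")

    def rate_matrix(self) -> np.ndarray:
        """HKY rate matrix in the internal base order A,G,C,T, scaled to
        one expected substitution per site per unit time."""
        fa, fc, fg, ft = self.freqs
        pi = np.array([fa, fg, fc, ft])  # A,G,C,T
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = (i < 2) == (j < 2)  # both purines or both pyrimidines
                q[i, j] = (self.kappa if transition else 1.0) * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate

    def stationary(self) -> np.ndarray:
        fa, fc, fg, ft = self.freqs
        return np.array([fa, fg, fc, ft])

    def category_rates(self) -> np.ndarray:
        """Mean rate of each of the equiprobable discrete-gamma categories."""
        a = self.gamma_shape
        k = self.n_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean of a Gamma(a, 1/a) truncated to [lo, hi], via the identity
        # E[X; X<t] = P(Gamma(a+1) < t) for a unit-mean gamma
        upper = gamma_dist.cdf(edges[1:], a + 1, scale=1.0 / a)
        lower = gamma_dist.cdf(edges[:-1], a + 1, scale=1.0 / a)
        return (upper - lower) * k


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class SpeciesTree:
    """Ultrametric species tree with divergence-time age classes."""

    def __init__(self, tree: dendropy.Tree, depth: float):
        self.tree = tree
        self.depth = float(depth)
        self._check_ultrametric()
        self.table = self._species_table()

    def _check_ultrametric(self) -> None:
        depths = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        vals = np.array(list(depths.values()))
        if np.any(np.abs(vals - self.depth) > 1e-6 * max(1.0, self.depth)):
            raise ValueError("species tree is not ultrametric at the stated depth")

    def _species_table(self):
        import pandas as pd

        rows = []
        for leaf in self.tree.leaf_node_iter():
            rows.append((leaf.taxon.label, float(leaf.edge.length)))
        df = pd.DataFrame(rows, columns=["species", "divergence_time"])
        df = df.sort_values(["divergence_time", "species"], kind="stable").reset_index(
            drop=True
        )
        half = len(df) // 2
        df["age_class"] = [AGE_RECENT] * half + [AGE_OLD] * (len(df) - half)
        return df.sort_values("species").reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def age_classes(self) -> dict[str, str]:
        return dict(zip(self.table["species"], self.table["age_class"]))

    def divergence_times(self) -> dict[str, float]:
        return dict(zip(self.table["species"], self.table["divergence_time"]))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


class GeneTree:
    """Per-individual tree whose tips carry species membership."""

    def __init__(self, tree: dendropy.Tree, species_map: dict[str, str]):
        self.tree = tree
        self.species_map = dict(species_map)

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "GeneTree":
        return GeneTree(self.tree.clone(depth=1), self.species_map)


def _species_label(i: int) -> str:
    return f"sp{i + 1:02d}"


def simulate_yule_tree(
    n_species: int, depth: float = 1e6, seed: int | None = None
) -> SpeciesTree:
    """Simulate an ultrametric Yule species tree conditioned on tip count.

    A forward pure-birth process (rate 1 per lineage) is run until
    ``n_species`` lineages exist, then observed one further exponential
    waiting time later (just before the next speciation would occur), and
    node ages are rescaled linearly so the root sits at ``depth``
    generations.  Leaves are labelled ``sp01..spNN``; the younger half by
    divergence time (terminal branch length) is classed recent, ties
    broken by label.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)

    # forward birth process; each extant lineage is a (node, birth_time)
    t = 0.0
    split_times = []
    root = {"children": [], "time": None}
    lineages = [root]
    while len(lineages) < n_species:
        k = len(lineages)
        t += rng.exponential(1.0 / k)
        split_times.append(t)
        idx = rng.integers(k)
        node = lineages[idx]
        node["time"] = t
        a = {"children": [], "time": None}
        b = {"children": [], "time": None}
        node["children"] = [a, b]
        lineages[idx] = a
        lineages.append(b)
    t_obs = t + rng.exponential(1.0 / n_species)
    t_root = split_times[0]
    scale = depth / (t_obs - t_root)

    # build newick via recursion, assigning labels in left-to-right order
    counter = {"i": 0}

    def build(node, parent_time):
        if not node["children"]:
            label = _species_label(counter["i"])
            counter["i"] += 1
            return f"{label}:{(t_obs - parent_time) * scale:.12g}"
        a, b = node["children"]
        inner = f"({build(a, node['time'])},{build(b, node['time'])})"
        if parent_time is None:
            return inner + ";"
        return f"{inner}:{(node['time'] - parent_time) * scale:.12g}"

    newick = build(root, None)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return SpeciesTree(tree, depth)


def _tskit_to_dendropy(ts_tree, labels: dict[int, str]) -> dendropy.Tree:
    """Convert a tskit tree to dendropy with branch lengths in generations."""
    parts = []

    def rec(u):
        children = ts_tree.children(u)
        t_u = ts_tree.time(u)
        if not children:
            return f"{labels[u]}", t_u
        subs = []
        for c in children:
            s, t_c = rec(c)
            subs.append(f"{s}:{t_u - t_c:.10f}")
        return "(" + ",".join(subs) + ")", t_u

    s, _ = rec(ts_tree.root)
    parts.append(s + ";")
    return dendropy.Tree.get(data="".join(parts), schema="newick", preserve_underscores=True)


def _demography_from_tree(st: SpeciesTree, pop_size: float) -> msprime.Demography:
    """msprime demography: one population per species-tree node, with
    population splits at the node ages (all populations share one Ne)."""
    dem = msprime.Demography()
    ages: dict[int, float] = {}
    names: dict[int, str] = {}
    counter = {"i": 0}
    for node in st.tree.preorder_node_iter():
        if node.parent_node is None:
            dfr = 0.0
        else:
            dfr = ages[id(node.parent_node)] + float(node.edge.length or 0.0)
        ages[id(node)] = dfr
    # convert distance-from-root to age above the leaves
    for node in st.tree.preorder_node_iter():
        ages[id(node)] = max(st.depth - ages[id(node)], 0.0)
    for node in st.tree.postorder_node_iter():
        if node.is_leaf():
            names[id(node)] = node.taxon.label
            dem.add_population(name=node.taxon.label, initial_size=pop_size)
        else:
            counter["i"] += 1
            name = f"anc{counter['i']:02d}"
            names[id(node)] = name
            dem.add_population(name=name, initial_size=pop_size)
    splits = []
    for node in st.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        splits.append(
            (
                ages[id(node)],
                [names[id(c)] for c in node.child_nodes()],
                names[id(node)],
            )
        )
    for time, derived, ancestral in sorted(splits, key=lambda s: s[0]):
        dem.add_population_split(time=time, derived=derived, ancestral=ancestral)
    return dem


def simulate_gene_tree(
    st: SpeciesTree, cp: CoalescentParams, seed: int | None = None
) -> GeneTree:
    """Simulate one multispecies-coalescent gene tree within ``st``.

    Lineages coalesce within each species-tree branch at rate
    ``k(k-1)/2 / (ploidy_factor * ne)`` per generation; lineages that fail
    to coalesce enter the ancestral branch, which uses the same Ne.
    The output tree is ultrametric with tips labelled
    ``{species}_{k:02d}``.
    """
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    demography = _demography_from_tree(st, cp.ploidy_factor * cp.ne)
    samples = {sp: cp.samples_per_species for sp in st.species}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        random_seed=ms_seed,
    )
    pop_names = {p.id: p.name for p in demography.populations}
    labels = {}
    species_map = {}
    counters = {sp: 0 for sp in st.species}
    for node_id in ts.samples():
        pop = ts.node(node_id).population
        sp = pop_names[pop]
        counters[sp] += 1
        label = f"{sp}_{counters[sp]:02d}"
        labels[node_id] = label
        species_map[label] = sp
    tree = _tskit_to_dendropy(ts.first(), labels)
    return GeneTree(tree, species_map)


def add_branch_noise(
    gt: GeneTree, noise: NoiseParams, seed: int | None = None
) -> GeneTree:
    """Return a copy of ``gt`` with noisy (generally non-ultrametric)
    branch lengths; topology is unchanged."""
    out = gt.copy()
    if noise.noise_factor == 0:
        return out
    rng = np.random.default_rng(seed)
    for edge in out.tree.preorder_edge_iter():
        if edge.length is None or edge.head_node.parent_node is None:
            continue
        b = float(edge.length)
        if b < 0:
            raise ValueError("negative branch length in input tree")
        if b == 0:
            continue
        new = -1.0
        for _ in range(noise.max_redraws):
            new = rng.normal(b, noise.noise_factor * b)
            if new >= 0:
                break
        edge.length = max(new, 0.0)
    return out


def simulate_sequences(
    gt: GeneTree, model: SubstitutionModel, seed: int | None = None
) -> BarcodeSet:
    """Simulate an alignment along ``gt`` under HKY+Gamma.

    The root sequence is drawn from the stationary frequencies; each site
    draws one of ``n_categories`` equiprobable category-mean rates which
    applies on every branch; substitution probabilities per branch are
    ``expm(Q * branch_length * rate_scale * category_rate)``.

    All individuals are returned with role ``reference``; use
    :func:`split_reference_query` to assign roles.
    """
    rng = np.random.default_rng(seed)
    q = model.rate_matrix()
    pi = model.stationary()
    rates = model.category_rates()
    L = model.length

    site_cat = rng.integers(model.n_categories, size=L)
    root_seq = rng.choice(4, size=L, p=pi).astype(np.uint8)

    seqs: dict[str, np.ndarray] = {}

    def evolve(parent_seq: np.ndarray, edge_len: float) -> np.ndarray:
        child = np.empty(L, dtype=np.uint8)
        for c in range(model.n_categories):
            t = edge_len * model.rate_scale * rates[c]
            p = expm(q * t) if t > 0 else np.eye(4)
            p = np.clip(p, 0, None)
            p /= p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            sites = np.where(site_cat == c)[0]
            if sites.size == 0:
                continue
            u = rng.random(sites.size)
            parent_states = parent_seq[sites]
            child[sites] = (u[:, None] > cum[parent_states]).sum(axis=1)
        return child

    root = gt.tree.seed_node
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf():
            seqs[node.taxon.label] = seq
            continue
        for ch in node.child_nodes():
            stack.append((ch, evolve(seq, float(ch.edge.length or 0.0))))

    records = []
    for label in sorted(seqs):
        records.append(
            (label, gt.species_map[label], ROLE_REFERENCE, decode_sequence(seqs[label]))
        )
    return BarcodeSet.from_records(records)


def split_reference_query(
    bs: BarcodeSet, n_ref: int = 16, n_query: int = 4, seed: int | None = None
) -> BarcodeSet:
    """Randomly partition each species' individuals into reference/query roles."""
    rng = np.random.default_rng(seed)
    df = bs.table.copy()
    roles = np.empty(len(df), dtype=object)
    for sp, idx in df.groupby("species").groups.items():
        idx = np.array(sorted(idx))
        if len(idx) != n_ref + n_query:
            raise ValueError(
                f"species {sp} has {len(idx)} individuals, expected {n_ref + n_query}"
            )
        perm = rng.permutation(len(idx))
        roles[idx[perm[:n_ref]]] = ROLE_REFERENCE
        roles[idx[perm[n_ref:]]] = ROLE_QUERY
    df["role"] = roles
    return BarcodeSet(df)


@dataclass
class SimulatedReplicate:
    """One fully simulated dataset plus the trees that produced it."""

    barcodes: BarcodeSet
    gene_tree: GeneTree
    noisy_tree: GeneTree
    species_tree: SpeciesTree


def simulate_replicate(
    st: SpeciesTree,
    cp: CoalescentParams,
    noise: NoiseParams,
    model: SubstitutionModel,
    n_ref: int = 16,
    n_query: int = 4,
    seed: int | None = None,
) -> SimulatedReplicate:
    """Full per-replicate chain: coalescent -> noise -> sequences -> split."""
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = rng.integers(1, 2**31 - 1, size=4)
    gt = simulate_gene_tree(st, cp, int(s1))
    noisy = add_branch_noise(gt, noise, int(s2))
    seqs = simulate_sequences(noisy, model, int(s3))
    bs = split_reference_query(seqs, n_ref, n_query, int(s4))
    return SimulatedReplicate(bs, gt, noisy, st)
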