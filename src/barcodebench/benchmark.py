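"""Replicated benchmark: success metrics, nonparametric method
comparison, and the empirical-dataset split procedure.

Identification success is measured two ways:

* species identification success — the fraction of species whose query
  sequences were *all* correctly identified (UNCERTAIN counts as
  failure);
* sequence identification success — correctly identified queries over
  all queries (sensitivity).

Methods are compared with Friedman tests (replicates as blocks) and
post-hoc pairwise Wilcoxon signed-rank tests with a global Bonferroni
correction (p-values multiplied by the total number of tests performed),
significant at corrected P < 0.01.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diagnostic_classifiers import DistinguisherClassifier, LogicFormulaClassifier
from .distances import barcode_gap_report, distance_matrix, species_monophyly
from .io import RunConfig, derive_seed
from .records import ROLE_QUERY, ROLE_REFERENCE, UNCERTAIN, BarcodeSet, Identification
from .simulate import (
    AGE_OLD,
    AGE_RECENT,
    CoalescentParams,
    NoiseParams,
    SpeciesTree,
    SubstitutionModel,
    simulate_replicate,
    simulate_yule_tree,
)
from .similarity_classifiers import LocalAlignmentClassifier, NearestNeighborClassifier
from .tree_classifiers import (
    NeighborJoiningClassifier,
    ParsimonyClassifier,
    TreeSearchParams,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# success metrics
# ---------------------------------------------------------------------------


def _as_frame(identifications, truth: dict[str, str]) -> pd.DataFrame:
    if isinstance(identifications, pd.DataFrame):
        df = identifications
    else:
        df = pd.DataFrame(
            [(i.query_id, i.assigned) for i in identifications],
            columns=["query_id", "assigned"],
        )
    df = df.copy()
    df["true_species"] = df["query_id"].map(truth)
    if df["true_species"].isna().any():
        missing = df.loc[df["true_species"].isna(), "query_id"].tolist()
        raise KeyError(f"queries without truth labels: {missing[:5]}")
    return df


def species_success(identifications, truth: dict[str, str],
                    species=None) -> tuple[float, int]:
    """Fraction (and count) of species with all queries correct."""
    df = _as_frame(identifications, truth)
    if species is not None:
        df = df[df["true_species"].isin(set(species))]
    ok = df.groupby("true_species").apply(
        lambda g: bool((g["assigned"] == g.name).all()),
        include_groups=False,
    )
    if len(ok) == 0:
        return np.nan, 0
    return float(ok.mean()), int(ok.sum())


def sequence_success(identifications, truth: dict[str, str],
                     species=None) -> float:
    """Correct queries / total queries (sensitivity); UNCERTAIN and
    misassignments both count against."""
    df = _as_frame(identifications, truth)
    if species is not None:
        df = df[df["true_species"].isin(set(species))]
    if len(df) == 0:
        return np.nan
    return float((df["assigned"] == df["true_species"]).mean())


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def friedman_test(table) -> tuple[float, float]:
    """Friedman chi-square test on a replicates x methods table.

    Within-replicate midranks with the standard tie correction; returns
    (statistic, p).  A table of identical columns gives (0, 1).
    """
    data = np.asarray(table, dtype=float)
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 methods and >= 2 replicates")
    ranks = np.vstack([sps.rankdata(row) for row in data])
    rsum = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rsum**2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * (k**3 - k))
    if c <= 0:
        return 0.0, 1.0
    stat /= c
    return float(stat), float(sps.chi2.sf(stat, k - 1))


def wilcoxon_posthoc(table: pd.DataFrame, correction_count: int | None = None,
                     alpha: float = 0.01) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests with Bonferroni correction.

    ``correction_count`` defaults to the number of pairs; pass the total
    number of tests performed across the whole analysis for a global
    correction.  Zero differences are dropped; the exact null is used for
    n <= 25 pairs, the normal approximation above.
    """
    cols = list(table.columns)
    pairs = list(combinations(cols, 2))
    if correction_count is None:
        correction_count = len(pairs)
    rows = []
    for a, b in pairs:
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        diffs = x - y
        diffs = diffs[diffs != 0]
        if diffs.size == 0:
            p = 1.0
        else:
            method = "exact" if diffs.size <= 25 else "approx"
            try:
                p = float(
                    sps.wilcoxon(x, y, zero_method="wilcox", method=method).pvalue
                )
            except ValueError:
                p = 1.0
        corrected = min(1.0, p * correction_count)
        rows.append((a, b, p, corrected, corrected < alpha))
    return pd.DataFrame(
        rows, columns=["method_a", "method_b", "p_raw", "p_corrected", "significant"]
    )


# ---------------------------------------------------------------------------
# empirical split
# ---------------------------------------------------------------------------


def empirical_split(bs: BarcodeSet, min_seqs: int = 5, ref_frac: float = 0.8,
                    seed: int | None = None) -> tuple[BarcodeSet, list[str]]:
    """80/20 reference/query split for species-labelled external data.

    Species with >= ``min_seqs`` sequences get a per-species random split
    with round((1-ref_frac)*n) queries (at least 1); species below the
    threshold stay entirely in the reference set and are excluded from
    evaluation (they can only contribute to false positives).  Returns
    the re-labelled set and the list of evaluated species.
    """
    rng = np.random.default_rng(seed)
    df = bs.table.copy()
    roles = np.full(len(df), ROLE_REFERENCE, dtype=object)
    evaluated = []
    for sp, idx in df.groupby("species").groups.items():
        idx = np.array(sorted(idx))
        if len(idx) < min_seqs:
            continue
        n_query = max(1, int(round((1.0 - ref_frac) * len(idx))))
        perm = rng.permutation(len(idx))
        roles[idx[perm[:n_query]]] = ROLE_QUERY
        evaluated.append(sp)
    df["role"] = roles
    return BarcodeSet(df), sorted(evaluated)


# ---------------------------------------------------------------------------
# benchmark runner
# ---------------------------------------------------------------------------

#: method tag -> (mode list) used by the runner
_TREE_MODES = ("liberal", "strict")


@dataclass
class BenchmarkResult:
    config: RunConfig
    success: pd.DataFrame
    assignments: pd.DataFrame
    gap: pd.DataFrame
    monophyly: pd.DataFrame
    species_table: pd.DataFrame

    def method_columns(self) -> list[str]:
        return sorted(
            {f"{m}|{mo}" for m, mo in zip(self.success["method"], self.success["mode"])}
        )

    def success_table(self, measure: str = "species_success",
                      age_class: str = "all", ne: float | None = None) -> pd.DataFrame:
        """Replicates x method|mode table of a success measure."""
        df = self.success[self.success["age_class"] == age_class]
        if ne is not None:
            df = df[df["ne"] == ne]
        df = df.copy()
        df["col"] = df["method"] + "|" + df["mode"]
        return df.pivot_table(
            index=["ne", "replicate"], columns="col", values=measure
        )

    def statistics_report(self, alpha: float = 0.01) -> str:
        """Friedman + global-Bonferroni Wilcoxon report on species success."""
        lines = []
        tables = []
        for age in (AGE_RECENT, AGE_OLD, "all"):
            tables.append((f"age={age}", self.success_table(age_class=age)))
        n_tests = sum(
            len(list(combinations(t.columns, 2))) + 1 for _, t in tables
        )
        for name, t in tables:
            stat, p = friedman_test(t)
            lines.append(f"[{name}] Friedman chi2={stat:.3f} p={min(1.0, p * n_tests):.2g} "
                         f"(corrected, {t.shape[0]} replicates x {t.shape[1]} methods)")
            ph = wilcoxon_posthoc(t, correction_count=n_tests, alpha=alpha)
            for row in ph.itertuples():
                flag = "*" if row.significant else " "
                lines.append(
                    f"  {row.method_a:>18} vs {row.method_b:<18} "
                    f"P={row.p_corrected:.3g} {flag}"
                )
        lines.append(f"(Bonferroni correction count = {n_tests} tests)")
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.success.to_csv(out / "success.tsv", sep="\t", index=False)
        self.assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        self.gap.to_csv(out / "gap.tsv", sep="\t", index=False)
        self.monophyly.to_csv(out / "monophyly.tsv", sep="\t", index=False)
        self.species_table.to_csv(out / "species.tsv", sep="\t", index=False)
        (out / "report.txt").write_text(self.statistics_report() + "\n")


def _build_matchers(config: RunConfig):
    out = {}
    for m in config.methods:
        if m == "nj":
            for mode in _TREE_MODES:
                out[("nj", mode)] = NeighborJoiningClassifier(mode=mode)
        elif m == "parsimony":
            params = TreeSearchParams(
                start_from_nj=True, max_iterations=config.parsimony_max_moves
            )
            for mode in _TREE_MODES:
                out[("parsimony", mode)] = ParsimonyClassifier(mode=mode, params=params)
        elif m == "nn":
            out[("nn", "n/a")] = NearestNeighborClassifier()
        elif m == "blast":
            out[("blast", "n/a")] = LocalAlignmentClassifier(band=config.sw_band)
        elif m == "dnabar":
            out[("dnabar", "n/a")] = DistinguisherClassifier(
                max_candidates=config.dnabar_max_candidates,
                redundancy=config.dnabar_redundancy,
            )
        elif m == "blog":
            out[("blog", "n/a")] = LogicFormulaClassifier(
                max_features=config.blog_max_features,
                max_disjuncts=config.blog_max_disjuncts,
            )
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def _tree_for_monophyly(matcher_outputs, refs, config, seed):
    """Reference-only NJ tree (queries ignored via the species map)."""
    from .tree_classifiers import build_nj_tree

    dm = distance_matrix(refs)
    return build_nj_tree(dm, seed=seed)


def run_benchmark(config: RunConfig, progress: bool = False) -> BenchmarkResult:
    """Run the full replicated simulation benchmark.

    Per replicate: simulate one dataset, hand the identical
    reference/query split to every matcher (paired design), score
    species- and sequence-level success by species age class, and record
    the per-species barcode-gap and NJ monophyly outcomes.  Replicates
    that fail are logged and dropped from all methods.
    """
    master = config.seed
    st = simulate_yule_tree(
        config.n_species, config.depth, derive_seed(master, "species_tree")
    )
    age_of = st.age_classes()
    recent = [s for s, a in age_of.items() if a == AGE_RECENT]
    old = [s for s, a in age_of.items() if a == AGE_OLD]
    noise = NoiseParams(config.noise_factor)
    model = SubstitutionModel(
        kappa=config.kappa, freqs=config.freqs, gamma_shape=config.gamma_shape,
        n_categories=config.n_categories, length=config.length,
        rate_scale=config.rate_scale,
    )
    matchers = _build_matchers(config)

    success_rows, assign_rows, gap_rows, mono_rows = [], [], [], []
    for ne_idx, ne in enumerate(config.ne_grid):
        cp = CoalescentParams(
            ne=ne, samples_per_species=config.samples_per_species,
            ploidy_factor=config.ploidy_factor,
        )
        for rep in range(config.replicates):
            t0 = time.time()
            rep_seed = derive_seed(master, "replicate", ne_idx, rep)
            if config.regenerate_species_tree:
                st_rep = simulate_yule_tree(
                    config.n_species, config.depth,
                    derive_seed(master, "species_tree", ne_idx, rep),
                )
            else:
                st_rep = st
            try:
                sim = simulate_replicate(
                    st_rep, cp, noise, model,
                    n_ref=config.n_ref, n_query=config.n_query, seed=rep_seed,
                )
                refs = sim.barcodes.references
                queries = sim.barcodes.queries
                truth = queries.truth()
                ref_seqs = refs.sequences()
                ref_labels = refs.labels()
                q_seqs = queries.sequences()
                q_ids = queries.ids()

                rep_assign = {}
                for (method, mode), matcher in matchers.items():
                    matcher.fit(ref_seqs, ref_labels)
                    ids = matcher.identify(q_seqs)
                    assigned = [i.assigned for i in ids]
                    rep_assign[(method, mode)] = assigned

                gap = barcode_gap_report(sim.barcodes)
                nj_ref_tree = _tree_for_monophyly(
                    rep_assign, refs, config, derive_seed(master, "mono", ne_idx, rep)
                )
                mono = species_monophyly(
                    nj_ref_tree,
                    dict(zip(refs.ids(), refs.labels())),
                )
            except Exception:
                logger.exception(
                    "replicate ne=%s rep=%d failed; dropped from all methods", ne, rep
                )
                continue

            for (method, mode), assigned in rep_assign.items():
                df = pd.DataFrame({"query_id": q_ids, "assigned": assigned})
                for age_name, subset in (
                    (AGE_RECENT, recent), (AGE_OLD, old), ("all", None)
                ):
                    sp_frac, sp_n = species_success(df, truth, subset)
                    seq_frac = sequence_success(df, truth, subset)
                    success_rows.append(
                        (ne, rep, method, mode, age_name, sp_frac, sp_n, seq_frac)
                    )
                for qid, a in zip(q_ids, assigned):
                    assign_rows.append(
                        (ne, rep, method, mode, qid, truth[qid], a,
                         age_of[truth[qid]])
                    )
            for row in gap.itertuples():
                gap_rows.append(
                    (ne, rep, row.species, age_of[row.species],
                     row.max_within, row.min_between, row.has_gap)
                )
            for sp, mono_ok in sorted(mono.items()):
                mono_rows.append((ne, rep, sp, age_of[sp], mono_ok))
            if progress:
                print(
                    f"ne={ne:>7g} rep={rep:>3d} done in {time.time() - t0:6.1f}s",
                    flush=True,
                )

    success = pd.DataFrame(
        success_rows,
        columns=["ne", "replicate", "method", "mode", "age_class",
                 "species_success", "n_species_correct", "sequence_success"],
    )
    assignments = pd.DataFrame(
        assign_rows,
        columns=["ne", "replicate", "method", "mode", "query_id",
                 "true_species", "assigned", "age_class"],
    )
    gap = pd.DataFrame(
        gap_rows,
        columns=["ne", "replicate", "species", "age_class", "max_within",
                 "min_between", "has_gap"],
    )
    mono = pd.DataFrame(
        mono_rows,
        columns=["ne", "replicate", "species", "age_class", "monophyletic"],
    )
    return BenchmarkResult(config, success, assignments, gap, mono, st.table)
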