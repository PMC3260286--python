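"""Pairwise K2P distances, barcode-gap scoring and species monophyly.

The Kimura two-parameter (K2P) distance separates transition (P) and
transversion (Q) proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

For saturated pairs where the log argument is non-positive the distance is
*undefined*; it is reported as NaN and downstream consumers treat it as
+infinity (nearest-neighbour) or exclude it with a warning (gap report).

A species has a *barcode gap* when its minimum between-species distance
strictly exceeds its maximum within-species distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import BarcodeSet, encode_sequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, valid sites) with pairwise deletion."""
    valid = (a < 4) & (b < 4)
    av, bv = a[valid], b[valid]
    diff = av != bv
    transition = diff & ((av >> 1) == (bv >> 1))
    p = int(transition.sum())
    q = int(diff.sum()) - p
    return p, q, int(valid.sum())


def k2p_from_proportions(p: float, q: float) -> float:
    arg = (1.0 - 2.0 * p - q) * np.sqrt(max(1.0 - 2.0 * q, 0.0))
    if arg <= 0:
        return np.nan
    return -0.5 * float(np.log(arg))


def k2p_distance(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """K2P distance between two equal-length sequences.

    Columns where either sequence is not an unambiguous A/C/G/T are
    excluded (pairwise deletion).  Returns NaN (undefined) when the
    distance formula saturates.
    """
    if isinstance(a, str):
        a = encode_sequence(a)
    if isinstance(b, str):
        b = encode_sequence(b)
    if a.shape != b.shape:
        raise ValueError(f"sequence length mismatch: {a.shape[0]} != {b.shape[0]}")
    p, q, n = _pq_counts(a, b)
    if n == 0:
        return np.nan
    return k2p_from_proportions(p / n, q / n)


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances (substitutions/site).

    Undefined (saturated) entries are NaN.
    """

    ids: list[str]
    data: np.ndarray
    model: str = "K2P"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match ids")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        iu = np.triu_indices(len(self.ids), k=1)
        for i, j in zip(*iu):
            if np.isnan(self.data[i, j]):
                out.append((self.ids[i], self.ids[j]))
        return out

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        pos = {x: i for i, x in enumerate(self.ids)}
        idx = np.array([pos[x] for x in ids])
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.model)

    def to_phylip(self) -> str:
        lines = [f"{len(self.ids)}"]
        for i, name in enumerate(self.ids):
            vals = " ".join(
                "NA" if np.isnan(v) else f"{v:.8f}" for v in self.data[i]
            )
            lines.append(f"{name}  {vals}")
        return "\n".join(lines) + "\n"


def k2p_pairwise_matrix(encoded: np.ndarray) -> np.ndarray:
    """All-pairs K2P on an (n, L) uint8 matrix; vectorised via matmuls."""
    n, L = encoded.shape
    valid = (encoded < 4).astype(np.float32)
    purine = ((encoded >> 1) == 0).astype(np.float32) * valid
    pyrimidine = valid - purine

    v = valid @ valid.T  # valid site counts
    match = np.zeros((n, n), dtype=np.float32)
    for base in range(4):
        x = (encoded == base).astype(np.float32)
        match += x @ x.T
    diff = v - match
    q_cnt = purine @ pyrimidine.T + pyrimidine @ purine.T
    p_cnt = diff - q_cnt

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(v > 0, p_cnt / v, np.nan)
        q = np.where(v > 0, q_cnt / v, np.nan)
        arg = (1.0 - 2.0 * p - q) * np.sqrt(np.clip(1.0 - 2.0 * q, 0.0, None))
        d = np.where(arg > 0, -0.5 * np.log(np.clip(arg, 1e-30, None)), np.nan)
    d = d.astype(float)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def distance_matrix(bs: BarcodeSet, role: str | None = None) -> DistanceMatrix:
    """All-pairs K2P distance matrix over the selected records."""
    sub = bs.subset(role=role) if role else bs
    enc = sub.encoded()
    return DistanceMatrix(sub.ids(), k2p_pairwise_matrix(enc))


# ---------------------------------------------------------------------------
# barcode gap
# ---------------------------------------------------------------------------


def barcode_gap_report(
    bs: BarcodeSet | None = None,
    dm: DistanceMatrix | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-species barcode-gap report on reference sequences.

    Columns: species, max_within, min_between, has_gap.  ``has_gap`` is
    True iff min_between strictly exceeds max_within (an exact tie counts
    as *no* gap).  Species with fewer than 2 reference sequences are
    excluded with a log message; undefined distances are excluded with a
    warning.
    """
    if dm is None:
        if bs is None:
            raise ValueError("provide a BarcodeSet or a DistanceMatrix + labels")
        refs = bs.references
        dm = distance_matrix(refs)
        labels = refs.labels()
    labels = np.asarray(labels)
    d = dm.data
    if np.isnan(d).any():
        logger.warning(
            "%d undefined distances excluded from gap report",
            int(np.isnan(d[np.triu_indices_from(d, k=1)]).sum()),
        )
    rows = []
    for sp in sorted(set(labels)):
        mask = labels == sp
        if mask.sum() < 2:
            logger.info("species %s has <2 reference sequences; excluded", sp)
            continue
        within = d[np.ix_(mask, mask)][np.triu_indices(int(mask.sum()), k=1)]
        between = d[np.ix_(mask, ~mask)].ravel()
        max_within = np.nanmax(within) if np.isfinite(within).any() else np.nan
        min_between = np.nanmin(between) if np.isfinite(between).any() else np.nan
        has_gap = bool(min_between > max_within) if not (
            np.isnan(max_within) or np.isnan(min_between)
        ) else False
        rows.append((sp, max_within, min_between, has_gap))
    return pd.DataFrame(rows, columns=["species", "max_within", "min_between", "has_gap"])


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------


def species_monophyly(tree, species_map: dict[str, str]) -> dict[str, bool]:
    """Unrooted monophyly of each species on ``tree`` (dendropy).

    A species is monophyletic iff some edge of the unrooted tree
    bipartitions exactly that species' tips from all others, i.e. some
    clade (or its complement) contains all and only that species' tips.
    Rooting-independent by construction.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    present = set(tips)
    totals: dict[str, int] = {}
    for label in tips:
        if label not in species_map:
            raise KeyError(f"tip {label} has no species label")
        totals[species_map[label]] = totals.get(species_map[label], 0) + 1
    for sp in set(species_map.values()):
        if sp not in totals:
            raise KeyError(f"species {sp} absent from tree")

    n_tips = len(tips)
    result = {sp: totals[sp] == 1 for sp in totals}  # singletons are trivially mono
    # postorder accumulation of (species counts restricted to candidate, size)
    counts: dict[int, dict[str, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[id(node)] = {species_map[node.taxon.label]: 1, "__size__": 1}
            continue
        acc: dict[str, int] = {"__size__": 0}
        for ch in node.child_nodes():
            for k, v in counts[id(ch)].items():
                acc[k] = acc.get(k, 0) + v
            del counts[id(ch)]
        counts[id(node)] = acc
        size = acc["__size__"]
        for sp, total in totals.items():
            cnt = acc.get(sp, 0)
            if cnt == total and size == total:
                result[sp] = True  # clade side
            if cnt == 0 and n_tips - size == total:
                result[sp] = True  # complement side
    return result
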