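"""Similarity-based identification: nearest neighbour and local-alignment
best hit.

*Nearest neighbour* assigns the species of the reference at minimal K2P
distance; a tie among conspecific references is still a confident
assignment, a minimal-distance tie spanning more than one species is
UNCERTAIN.  Undefined (saturated) distances act as +infinity.

*Local-alignment best hit* emulates BLAST-style matching with an exact
affine-gap Smith-Waterman (match +2, mismatch -3, gap open 5, extend 2):
up to 100 hits with >= 80% alignment identity are retained per query and
the species of the top-scoring qualifying hit is assigned; a top-score
tie across species, or no qualifying hit, is UNCERTAIN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._sw import sw_align_banded, sw_scores_banded
from .records import UNCERTAIN, Identification, encode_sequence

logger = logging.getLogger(__name__)


def _k2p_rect(qenc: np.ndarray, renc: np.ndarray) -> np.ndarray:
    """Rectangular K2P block (queries x references); NaN where undefined."""
    valid_q = (qenc < 4).astype(np.float32)
    valid_r = (renc < 4).astype(np.float32)
    pur_q = ((qenc >> 1) == 0).astype(np.float32) * valid_q
    pur_r = ((renc >> 1) == 0).astype(np.float32) * valid_r
    pyr_q = valid_q - pur_q
    pyr_r = valid_r - pur_r
    v = valid_q @ valid_r.T
    match = np.zeros(v.shape, dtype=np.float32)
    for base in range(4):
        match += (qenc == base).astype(np.float32) @ (renc == base).astype(np.float32).T
    diff = v - match
    q_cnt = pur_q @ pyr_r.T + pyr_q @ pur_r.T
    p_cnt = diff - q_cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(v > 0, p_cnt / v, np.nan)
        q = np.where(v > 0, q_cnt / v, np.nan)
        arg = (1.0 - 2.0 * p - q) * np.sqrt(np.clip(1.0 - 2.0 * q, 0.0, None))
        d = np.where(arg > 0, -0.5 * np.log(np.clip(arg, 1e-30, None)), np.nan)
    return d.astype(float)


class NearestNeighborClassifier(BaseEstimator, ClassifierMixin):
    """K2P nearest-neighbour (best match) barcode matcher."""

    _method_name = "nn"

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y)
        self.reference_encoded_ = np.vstack([encode_sequence(s) for s in X])
        self.reference_labels_ = y
        self.classes_ = np.unique(y)
        return self

    def identify(self, X) -> list[Identification]:
        X = list(X)
        qenc = np.vstack([encode_sequence(s) for s in X])
        d = _k2p_rect(qenc, self.reference_encoded_)
        d = np.where(np.isnan(d), np.inf, d)
        out = []
        for i in range(len(X)):
            row = d[i]
            mn = row.min()
            if not np.isfinite(mn):
                logger.warning("query %d: all distances undefined", i)
                out.append(Identification(f"q{i}", UNCERTAIN, self._method_name))
                continue
            hit_species = set(self.reference_labels_[row == mn])
            assigned = hit_species.pop() if len(hit_species) == 1 else UNCERTAIN
            out.append(Identification(f"q{i}", assigned, self._method_name))
        return out

    def predict(self, X):
        return np.array([i.assigned for i in self.identify(X)], dtype=object)


def nn_identify(query: str, references: list[str], labels) -> Identification:
    """Identify one query against labelled reference sequences (K2P NN)."""
    clf = NearestNeighborClassifier().fit(references, labels)
    return clf.identify([query])[0]


@dataclass
class Hit:
    reference_index: int
    score: int
    identity: float


class LocalAlignmentClassifier(BaseEstimator, ClassifierMixin):
    """Local-alignment best-hit (BLAST-like) barcode matcher.

    Exact Smith-Waterman with affine gaps; ``band`` limits the alignment
    to diagonals within +-band of the main diagonal (``None`` computes the
    full matrix).  ``min_identity`` is the identity floor for a hit to
    qualify (matches / alignment columns).
    """

    _method_name = "blast"

    def __init__(self, match: int = 2, mismatch: int = -3, gap_open: int = 5,
                 gap_extend: int = 2, min_identity: float = 0.8,
                 band: int | None = 32, max_hits: int = 100):
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.min_identity = min_identity
        self.band = band
        self.max_hits = max_hits

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y)
        self.reference_sequences_ = X
        self.reference_labels_ = y
        self.classes_ = np.unique(y)
        # dedupe identical reference sequences: identical strings share
        # scores, so one alignment per unique sequence suffices
        uniq: dict[str, list[int]] = {}
        for i, s in enumerate(X):
            uniq.setdefault(s, []).append(i)
        self._unique_seqs = list(uniq)
        self._unique_members = [uniq[s] for s in self._unique_seqs]
        self._unique_enc = np.vstack(
            [encode_sequence(s) for s in self._unique_seqs]
        ).astype(np.int8)
        return self

    def _band_for(self, n: int, m: int) -> int:
        if self.band is None:
            return max(n, m)
        return self.band

    def _scores(self, qenc: np.ndarray) -> np.ndarray:
        band = self._band_for(qenc.shape[0], self._unique_enc.shape[1])
        return sw_scores_banded(
            qenc, self._unique_enc, band, self.match, self.mismatch,
            self.gap_open + self.gap_extend, self.gap_extend,
        )

    def _identity(self, qenc: np.ndarray, uidx: int) -> float:
        band = self._band_for(qenc.shape[0], self._unique_enc.shape[1])
        _, matches, cols = sw_align_banded(
            qenc, self._unique_enc[uidx], band, self.match, self.mismatch,
            self.gap_open + self.gap_extend, self.gap_extend,
        )
        return matches / cols if cols else 0.0

    def hits(self, query: str) -> list[Hit]:
        """Ranked qualifying hits (score desc), at most ``max_hits``."""
        qenc = encode_sequence(query).astype(np.int8)
        scores = self._scores(qenc)
        order = np.argsort(-scores, kind="stable")
        out = []
        for uidx in order:
            if scores[uidx] <= 0 or len(out) >= self.max_hits:
                break
            ident = self._identity(qenc, int(uidx))
            if ident < self.min_identity:
                continue
            for ref_i in self._unique_members[uidx]:
                if len(out) >= self.max_hits:
                    break
                out.append(Hit(ref_i, int(scores[uidx]), ident))
        return out

    def hits_tsv(self, queries: dict[str, str]) -> str:
        """Hit lists in a BLAST outfmt-6-like TSV (qseqid, sseqid, pident,
        score), one block per query, ranked by score."""
        lines = ["qseqid\tsseqid\tpident\tscore"]
        for qid, seq in queries.items():
            for h in self.hits(seq):
                lines.append(
                    f"{qid}\t{h.reference_index}\t{100 * h.identity:.2f}\t{h.score}"
                )
        return "\n".join(lines) + "\n"

    def identify(self, X) -> list[Identification]:
        X = list(X)
        # dedupe queries as well: identical queries get identical results
        cache: dict[str, str] = {}
        out = []
        for i, s in enumerate(X):
            if s not in cache:
                cache[s] = self._identify_one(s)
            out.append(Identification(f"q{i}", cache[s], self._method_name))
        return out

    def _identify_one(self, query: str) -> str:
        qenc = encode_sequence(query).astype(np.int8)
        scores = self._scores(qenc)
        order = np.argsort(-scores, kind="stable")
        pos = 0
        # walk score levels from the top until one has a qualifying hit
        while pos < order.size:
            sc = int(scores[order[pos]])
            if sc <= 0:
                return UNCERTAIN
            tied = [int(u) for u in order[pos:] if scores[u] == sc]
            qualifying = [
                u for u in tied if self._identity(qenc, u) >= self.min_identity
            ]
            if qualifying:
                species = set()
                for u in qualifying:
                    for ref_i in self._unique_members[u]:
                        species.add(self.reference_labels_[ref_i])
                return species.pop() if len(species) == 1 else UNCERTAIN
            pos += len(tied)
        return UNCERTAIN

    def predict(self, X):
        return np.array([i.assigned for i in self.identify(X)], dtype=object)


def local_align_identify(query: str, references: list[str], labels,
                         min_identity: float = 0.8,
                         band: int | None = None) -> Identification:
    """Identify one query by best local-alignment hit (full SW by default)."""
    clf = LocalAlignmentClassifier(min_identity=min_identity, band=band)
    clf.fit(references, labels)
    return clf.identify([query])[0]
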