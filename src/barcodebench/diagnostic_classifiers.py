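"""Diagnostic identification: substring distinguishers and per-species
logic formulas.

The *distinguisher* matcher is alignment-free: it greedily selects
substrings (length 5-50) of the reference sequences so that every pair of
distinct reference sequences differs in the presence/absence of at least
``redundancy`` selected substrings (greedy set cover with lazy marginal
evaluation).  A query is scored against every reference's
presence/absence profile and assigned the species of the best-agreeing
reference(s); a best-score tie across species is UNCERTAIN.

The *logic-formula* matcher is alignment-bound and species-level: for
each species it selects up to ``max_features`` diagnostic alignment
columns, then greedily grows conjunctions of ``position = nucleotide``
literals that exclude all other species' sequences while covering its
own (sequential covering, up to ``max_disjuncts`` conjunctions).  A
query satisfying exactly one species' formula is assigned that species;
among multiple satisfied formulas the lowest training false-positive
rate wins, with ties UNCERTAIN.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import UNCERTAIN, Identification, encode_sequence, decode_sequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DNA-BAR style distinguishers
# ---------------------------------------------------------------------------


class DistinguisherClassifier(BaseEstimator, ClassifierMixin):
    """Substring-distinguisher (presence/absence profile) matcher."""

    _method_name = "dnabar"

    def __init__(self, lengths: tuple[int, ...] = (5, 8, 12, 20),
                 max_candidates: int = 50000, redundancy: int = 3,
                 random_state: int | None = 0):
        self.lengths = lengths
        self.max_candidates = max_candidates
        self.redundancy = redundancy
        self.random_state = random_state

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y)
        if any(not (5 <= l <= 50) for l in self.lengths):
            raise ValueError("distinguisher lengths must be within [5, 50]")
        uniq: dict[str, list[int]] = {}
        for i, s in enumerate(X):
            uniq.setdefault(s, []).append(i)
        self._unique_seqs = list(uniq)
        self._unique_species = [
            sorted({y[i] for i in uniq[s]}) for s in self._unique_seqs
        ]
        for seq, specs in zip(self._unique_seqs, self._unique_species):
            if len(specs) > 1:
                logger.warning(
                    "identical sequence shared by species %s: inseparable", specs
                )
        u = len(self._unique_seqs)
        self.reference_labels_ = y
        self.classes_ = np.unique(y)

        candidates = self._candidate_pool()
        presence = self._presence_matrix(candidates)  # (ncand, u) bool
        self.distinguishers_, self.profiles_ = self._greedy_cover(
            candidates, presence, u
        )
        return self

    def _candidate_pool(self) -> list[str]:
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(self._unique_seqs))
        pool: dict[str, None] = {}
        for idx in order:
            seq = self._unique_seqs[idx]
            for l in self.lengths:
                for start in range(len(seq) - l + 1):
                    pool.setdefault(seq[start:start + l])
            if len(pool) >= self.max_candidates:
                break
        return list(pool)

    def _presence_matrix(self, candidates: list[str]) -> np.ndarray:
        by_len: dict[int, dict[str, int]] = {}
        for ci, c in enumerate(candidates):
            by_len.setdefault(len(c), {})[c] = ci
        u = len(self._unique_seqs)
        presence = np.zeros((len(candidates), u), dtype=bool)
        for r, seq in enumerate(self._unique_seqs):
            for l, index in by_len.items():
                for start in range(len(seq) - l + 1):
                    ci = index.get(seq[start:start + l])
                    if ci is not None:
                        presence[ci, r] = True
        return presence

    def _greedy_cover(self, candidates, presence, u):
        """Lazy-greedy set cover of sequence pairs to ``redundancy``."""
        if u < 2 or not candidates:
            if u >= 2:
                logger.warning("no distinguisher candidates; degenerate set")
            return [], np.zeros((0, u), dtype=bool)
        # candidates with identical presence profiles are interchangeable
        first_of: dict[bytes, int] = {}
        for ci in range(presence.shape[0]):
            first_of.setdefault(presence[ci].tobytes(), ci)
        cand_idx = sorted(first_of.values())
        prof = presence[cand_idx]

        iu, ju = np.triu_indices(u, k=1)
        remaining = np.full(iu.shape[0], self.redundancy, dtype=np.int16)
        ii, jj = iu, ju  # the still-active (not fully covered) pairs
        rem_active = remaining
        k = prof.sum(axis=1)
        bound = k * (u - k)  # upper bound on separable pairs
        heap = [(-int(b), pi) for pi, b in enumerate(bound) if b > 0]
        heapq.heapify(heap)
        chosen: list[int] = []
        while heap and ii.size:
            _, pi = heapq.heappop(heap)
            mem = prof[pi]
            gain = int((mem[ii] != mem[jj]).sum())
            if gain == 0:
                continue
            if heap and -heap[0][0] > gain:
                heapq.heappush(heap, (-gain, pi))
                continue
            chosen.append(pi)
            sep = mem[ii] != mem[jj]
            rem_active = rem_active - sep
            keep = rem_active > 0
            ii, jj, rem_active = ii[keep], jj[keep], rem_active[keep]
        if ii.size:
            never = int((rem_active == self.redundancy).sum())
            if never:
                logger.info("%d sequence pairs not separated by any candidate", never)
        return [candidates[cand_idx[pi]] for pi in chosen], prof[chosen]

    def matrix_tsv(self) -> str:
        """Presence/absence (0/1) matrix of distinguishers over the unique
        reference sequences."""
        header = "distinguisher\t" + "\t".join(
            f"u{i}" for i in range(len(self._unique_seqs))
        )
        lines = [header]
        for d, row in zip(self.distinguishers_, self.profiles_):
            lines.append(d + "\t" + "\t".join("1" if v else "0" for v in row))
        return "\n".join(lines) + "\n"

    def query_profile(self, query: str) -> np.ndarray:
        return np.array([d in query for d in self.distinguishers_], dtype=bool)

    def identify(self, X) -> list[Identification]:
        X = list(X)
        cache: dict[str, str] = {}
        out = []
        for i, s in enumerate(X):
            if s not in cache:
                cache[s] = self._identify_one(s)
            out.append(Identification(f"q{i}", cache[s], self._method_name))
        return out

    def _identify_one(self, query: str) -> str:
        prof = self.query_profile(query)
        if self.profiles_.shape[0] == 0:
            return UNCERTAIN
        agree = (self.profiles_ == prof[:, None]).sum(axis=0)
        best = agree.max()
        species = set()
        for uidx in np.where(agree == best)[0]:
            species.update(self._unique_species[uidx])
        return species.pop() if len(species) == 1 else UNCERTAIN

    def predict(self, X):
        return np.array([i.assigned for i in self.identify(X)], dtype=object)


def select_distinguishers(references, labels, **kwargs) -> DistinguisherClassifier:
    """Fit a distinguisher set on labelled references (spec operation)."""
    return DistinguisherClassifier(**kwargs).fit(references, labels)


def dnabar_identify(query: str, ds: DistinguisherClassifier) -> Identification:
    return ds.identify([query])[0]


# ---------------------------------------------------------------------------
# BLOG style logic formulas
# ---------------------------------------------------------------------------


@dataclass
class LogicFormula:
    """Disjunction of conjunctions of ``column == base`` literals."""

    species: str
    conjunctions: list[list[tuple[int, str]]]
    fp_rate: float
    fn_rate: float

    def satisfied(self, seq: str) -> bool:
        return any(
            all(seq[c] == b for c, b in conj) for conj in self.conjunctions
        )

    def describe(self) -> str:
        """Human-readable species description (0-based columns)."""
        parts = [
            " AND ".join(f"pos{c}={b}" for c, b in conj)
            for conj in self.conjunctions
        ]
        return f"{self.species}: " + " OR ".join(f"({p})" for p in parts)


class LogicFormulaClassifier(BaseEstimator, ClassifierMixin):
    """Per-species logic-formula (diagnostic character) matcher."""

    _method_name = "blog"

    def __init__(self, max_features: int = 35, max_disjuncts: int = 5):
        self.max_features = max_features
        self.max_disjuncts = max_disjuncts

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y)
        enc = np.vstack([encode_sequence(s) for s in X])
        self.alignment_length_ = enc.shape[1]
        self.classes_ = np.unique(y)
        self.formulas_ = {}
        for sp in self.classes_:
            self.formulas_[sp] = self._learn_species(enc, y, sp)
        return self

    def _learn_species(self, enc: np.ndarray, y: np.ndarray, sp: str) -> LogicFormula:
        is_x = y == sp
        xmat = enc[is_x]
        nmat = enc[~is_x]
        n_x, n_n = xmat.shape[0], nmat.shape[0]
        cols = self._select_features(xmat, nmat)

        conjunctions: list[list[tuple[int, str]]] = []
        uncovered = np.ones(n_x, dtype=bool)
        while uncovered.any() and len(conjunctions) < self.max_disjuncts:
            conj, covered = self._grow_conjunction(xmat, nmat, cols, uncovered)
            if not conj:
                break
            conjunctions.append(conj)
            newly = covered & uncovered
            if not newly.any():
                break
            uncovered &= ~covered
        if not conjunctions:
            conjunctions = [[]]  # degenerate: satisfied by everything

        sat_x = np.zeros(n_x, dtype=bool)
        sat_n = np.zeros(n_n, dtype=bool)
        for conj in conjunctions:
            cx = np.ones(n_x, dtype=bool)
            cn = np.ones(n_n, dtype=bool)
            for c, b in conj:
                code = encode_sequence(b)[0]
                cx &= xmat[:, c] == code
                cn &= nmat[:, c] == code
            sat_x |= cx
            sat_n |= cn
        fp = float(sat_n.mean()) if n_n else 0.0
        fn = float((~sat_x).mean()) if n_x else 0.0
        return LogicFormula(sp, conjunctions, fp, fn)

    def _select_features(self, xmat: np.ndarray, nmat: np.ndarray) -> np.ndarray:
        """Columns ranked by separating-pair count of their best base."""
        n_n = nmat.shape[0]
        L = xmat.shape[1]
        scores = np.zeros(L, dtype=np.int64)
        for v in range(4):
            nx_v = (xmat == v).sum(axis=0)
            nn_v = (nmat == v).sum(axis=0)
            scores = np.maximum(scores, nx_v * (n_n - nn_v))
        order = np.argsort(-scores, kind="stable")
        return order[: self.max_features]

    def _grow_conjunction(self, xmat, nmat, cols, uncovered):
        """Greedy literal selection: maximise excluded non-target
        sequences, tie-break on retained target sequences."""
        t_mask = uncovered.copy()  # target X seqs still satisfying the conj
        r_mask = np.ones(nmat.shape[0], dtype=bool)  # non-X still satisfying
        conj: list[tuple[int, str]] = []
        used_cols: set[int] = set()
        while r_mask.any():
            best = None  # (gain, retained, -col, -base, c, v)
            for c in cols:
                ci = int(c)
                if ci in used_cols:
                    continue
                for v in range(4):
                    newt = int((t_mask & (xmat[:, ci] == v)).sum())
                    if newt == 0:
                        continue
                    newr = int((r_mask & (nmat[:, ci] == v)).sum())
                    gain = int(r_mask.sum()) - newr
                    key = (gain, newt, -ci, -v)
                    if best is None or key > best[0]:
                        best = (key, ci, v)
            if best is None:
                break
            (gain, _, _, _), ci, v = best
            if gain == 0 and conj:
                break  # later literals must make progress
            base = decode_sequence(np.array([v], dtype=np.uint8))
            conj.append((ci, base))
            used_cols.add(ci)
            t_mask &= xmat[:, ci] == v
            r_mask &= nmat[:, ci] == v
            if gain == 0:
                break  # first literal made no progress: inseparable
        covered = np.ones(xmat.shape[0], dtype=bool)
        for c, b in conj:
            code = encode_sequence(b)[0]
            covered &= xmat[:, c] == code
        return conj, covered

    def identify(self, X) -> list[Identification]:
        X = list(X)
        out = []
        for i, s in enumerate(X):
            if len(s) != self.alignment_length_:
                raise ValueError(
                    "query length does not match reference alignment "
                    f"({len(s)} != {self.alignment_length_})"
                )
            matches = [
                f for f in self.formulas_.values() if f.satisfied(s)
            ]
            if not matches:
                assigned = UNCERTAIN
            elif len(matches) == 1:
                assigned = matches[0].species
            else:
                fps = sorted(m.fp_rate for m in matches)
                if fps[0] < fps[1]:
                    assigned = min(matches, key=lambda m: m.fp_rate).species
                else:
                    assigned = UNCERTAIN
            out.append(Identification(f"q{i}", assigned, self._method_name))
        return out

    def predict(self, X):
        return np.array([i.assigned for i in self.identify(X)], dtype=object)

    def describe(self) -> str:
        return "\n".join(f.describe() for f in self.formulas_.values())

    def to_tsv(self) -> str:
        """species, disjunct index, literal list col:base (0-based), fp, fn."""
        lines = ["# 0-based alignment columns",
                 "species\tdisjunct\tliterals\tfp_rate\tfn_rate"]
        for f in self.formulas_.values():
            for di, conj in enumerate(f.conjunctions):
                lits = ",".join(f"{c}:{b}" for c, b in conj)
                lines.append(
                    f"{f.species}\t{di}\t{lits}\t{f.fp_rate:.4f}\t{f.fn_rate:.4f}"
                )
        return "\n".join(lines) + "\n"


def learn_logic_formulas(references, labels, **kwargs) -> LogicFormulaClassifier:
    """Train per-species logic formulas (spec operation)."""
    return LogicFormulaClassifier(**kwargs).fit(references, labels)


def blog_identify(query: str, formulas: LogicFormulaClassifier) -> Identification:
    return formulas.identify([query])[0]
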