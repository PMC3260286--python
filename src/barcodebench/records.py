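"""Core containers for barcode datasets and identification results.

A :class:`BarcodeSet` holds aligned (or at least co-typed) DNA barcode
sequences together with the individual they were sampled from, the species
they truly belong to, and their role in an identification experiment:
``reference`` sequences form the library with a priori known species
membership, ``query`` sequences are the unknowns to be identified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Distinguished assignment state for queries that cannot be identified.
UNCERTAIN = "UNCERTAIN"

ROLE_REFERENCE = "reference"
ROLE_QUERY = "query"

# Internal nucleotide encoding.  Purines first, pyrimidines second, so that
# two codes are a transition pair iff they share the high bit: A<->G, C<->T.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_BASE = np.array(["A", "G", "C", "T"], dtype="U1")
#: Code used for anything that is not an unambiguous A/C/G/T (gap, N, IUPAC
#: ambiguity).  Such columns are excluded pairwise in distance computations.
MISSING = 255

_IUPAC = set("ACGTRYSWKMBDHVN-?")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0,G=1,C=2,T=3).

    Non-ACGT IUPAC symbols map to :data:`MISSING`.  Lower case is accepted.
    """
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    arr = np.full(len(seq), MISSING, dtype=np.uint8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype="S1") == base.encode()] = code
    return arr


def decode_sequence(arr: np.ndarray) -> str:
    out = np.full(arr.shape, "N", dtype="U1")
    ok = arr < 4
    out[ok] = _BASE[arr[ok]]
    return "".join(out)


@dataclass(frozen=True)
class Identification:
    """Species assignment for one query sequence.

    ``assigned`` is either a species label present in the reference set or
    the distinguished state :data:`UNCERTAIN`.  ``mode`` is ``strict`` or
    ``liberal`` for tree-based methods and ``n/a`` otherwise.
    """

    query_id: str
    assigned: str
    method: str
    mode: str = "n/a"

    @property
    def is_uncertain(self) -> bool:
        return self.assigned == UNCERTAIN


class BarcodeSet:
    """A table of barcode records (individual, species, role, sequence)."""

    def __init__(self, table: pd.DataFrame):
        required = {"individual_id", "species", "role", "sequence"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if table["individual_id"].duplicated().any():
            dup = table["individual_id"][table["individual_id"].duplicated()]
            raise ValueError(f"duplicate individual ids: {sorted(set(dup))}")
        lengths = table["sequence"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self._table = table.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str, str]],
    ) -> "BarcodeSet":
        """Build from ``(individual_id, species, role, sequence)`` tuples."""
        df = pd.DataFrame(
            list(records), columns=["individual_id", "species", "role", "sequence"]
        )
        df["sequence"] = df["sequence"].str.upper()
        return cls(df)

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def alignment_length(self) -> int:
        if len(self._table) == 0:
            return 0
        return len(self._table["sequence"].iloc[0])

    @property
    def species(self) -> list[str]:
        return sorted(self._table["species"].unique())

    def __len__(self) -> int:
        return len(self._table)

    def subset(self, role: str | None = None, species: Sequence[str] | None = None) -> "BarcodeSet":
        df = self._table
        if role is not None:
            df = df[df["role"] == role]
        if species is not None:
            df = df[df["species"].isin(species)]
        return BarcodeSet(df.copy())

    @property
    def references(self) -> "BarcodeSet":
        return self.subset(role=ROLE_REFERENCE)

    @property
    def queries(self) -> "BarcodeSet":
        return self.subset(role=ROLE_QUERY)

    def sequences(self) -> list[str]:
        return self._table["sequence"].tolist()

    def ids(self) -> list[str]:
        return self._table["individual_id"].tolist()

    def labels(self) -> np.ndarray:
        return self._table["species"].to_numpy()

    def encoded(self) -> np.ndarray:
        """Sequences as an (n, L) uint8 matrix in the internal encoding."""
        if len(self._table) == 0:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.vstack([encode_sequence(s) for s in self._table["sequence"]])

    def truth(self) -> dict[str, str]:
        """individual_id -> true species."""
        return dict(zip(self._table["individual_id"], self._table["species"]))
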