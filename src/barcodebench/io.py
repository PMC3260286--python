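"""Readers/writers (FASTA, Newick, TSV), run configuration and seeding.

Internal FASTA headers follow ``>{species}|{individual}|{role}``.  External
species-labelled FASTA can be read with a separate TSV mapping file
(``sequence_id<TAB>species``).  All stochastic stages derive their seeds
deterministically from a single master seed plus a stage tag, so full
pipeline reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ROLE_REFERENCE, BarcodeSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------


def derive_seed(master: int, *tags) -> int:
    """Deterministic child seed (< 2^31) from a master seed and stage tags."""
    key = [int(master) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            key.append(zlib.crc32(tag.encode()))
        else:
            key.append(int(tag) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(bs: BarcodeSet, path: str | Path) -> None:
    records = []
    for row in bs.table.itertuples():
        rid = f"{row.species}|{row.individual_id}|{row.role}"
        records.append(SeqRecord(Seq(row.sequence), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, mapping: str | Path | None = None) -> BarcodeSet:
    """Read FASTA into a BarcodeSet.

    Headers of the form ``species|individual|role`` are parsed directly;
    otherwise a mapping TSV (``sequence_id<TAB>species``) must be given and
    all records become references.  Sequences are normalised to upper case.
    """
    species_of = {}
    if mapping is not None:
        for line in Path(mapping).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            sid, sp = line.split("\t")[:2]
            species_of[sid] = sp
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3:
            sp, ind, role = parts
        elif rec.id in species_of:
            sp, ind, role = species_of[rec.id], rec.id, ROLE_REFERENCE
        else:
            raise ValueError(
                f"cannot determine species for record {rec.id!r}: "
                "use species|individual|role headers or a mapping file"
            )
        rows.append((ind, sp, role, str(rec.seq).upper()))
    if not rows:
        logger.warning("empty FASTA file: %s", path)
        import pandas as pd

        return BarcodeSet(
            pd.DataFrame(columns=["individual_id", "species", "role", "sequence"])
        )
    return BarcodeSet.from_records(rows)


def write_truth_table(bs: BarcodeSet, path: str | Path) -> None:
    bs.table[["individual_id", "species", "role"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (from a path or a literal string)."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        data = s
    else:
        data = Path(path_or_string).read_text()
    try:
        return dendropy.Tree.get(
            data=data, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise ValueError(f"malformed Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All simulator/matcher/benchmark parameters plus the master seed.

    Defaults are the benchmark's study conditions: a 50-species Yule tree
    of depth 1e6 generations, 20 individuals per species at Ne in
    {1000, 10000, 50000}, branch noise 0.7, HKY kappa 8.3 with
    frequencies (.30,.15,.10,.45), gamma shape 0.2 (4 categories),
    650 bp, split 16 reference / 4 query per species.
    """

    n_species: int = 50
    depth: float = 1e6
    ne_grid: tuple[float, ...] = (1000.0, 10000.0, 50000.0)
    samples_per_species: int = 20
    ploidy_factor: int = 1
    n_ref: int = 16
    n_query: int = 4
    noise_factor: float = 0.7
    kappa: float = 8.3
    freqs: tuple[float, float, float, float] = (0.30, 0.15, 0.10, 0.45)
    gamma_shape: float = 0.2
    n_categories: int = 4
    length: int = 650
    rate_scale: float = 5e-8
    replicates: int = 10
    methods: tuple[str, ...] = ("nj", "parsimony", "nn", "blast", "dnabar", "blog")
    regenerate_species_tree: bool = False
    sw_band: int = 32
    dnabar_redundancy: int = 3
    dnabar_max_candidates: int = 50000
    blog_max_features: int = 35
    blog_max_disjuncts: int = 5
    parsimony_max_moves: int = 60
    seed: int = 1

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("ne_grid", "freqs", "methods"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
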