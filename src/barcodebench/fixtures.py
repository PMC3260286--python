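"""Packaged toy fixture: two recently diverged sister species.

The fixture encodes the textbook failure case for similarity- and
tree-based barcode matching: two sister species that share two
polymorphic positions but differ by a single fixed diagnostic
nucleotide, plus a distant outgroup species.

Layout (alignment length 20, 0-based columns):

* column 0 — the fixed diagnostic: species1 = A, species2 = G,
  species3 = T;
* columns 10 and 15 — polymorphisms (C/T) shared by species1 and
  species2, so that some haplotypes of species1 are closer to species2
  haplotypes than to their own conspecifics;
* columns 3-5 — fixed differences that set the outgroup species3 apart.

Expected behaviour, asserted in the test suite: the per-species
logic-formula classifier learns one-literal formulas (column 0) with zero
training error and identifies every haplotype correctly, while
nearest-neighbour matching misassigns or abstains on some haplotypes and
neighbor-joining groups haplotypes across the species boundary.  The
substring-distinguisher method scores per-sequence profiles and inherits
the same haplotype confusion as nearest neighbour on data of this shape.
No barcode gap exists for species1/species2.
"""

from __future__ import annotations

from .records import ROLE_REFERENCE, BarcodeSet


def _seq(diag: str, out3: str, p10: str, p15: str) -> str:
    base = list("CCCCCCCCCCCCCCCCCCCC")
    base[0] = diag
    base[3] = base[4] = base[5] = out3
    base[10] = p10
    base[15] = p15
    return "".join(base)


def fig1_fixture() -> BarcodeSet:
    """Toy alignment of three species; all records have role reference."""
    rows = [
        ("s1a", "species1", ROLE_REFERENCE, _seq("A", "C", "C", "C")),
        ("s1b", "species1", ROLE_REFERENCE, _seq("A", "C", "T", "T")),
        ("s2a", "species2", ROLE_REFERENCE, _seq("G", "C", "C", "C")),
        ("s2b", "species2", ROLE_REFERENCE, _seq("G", "C", "T", "C")),
        ("s3a", "species3", ROLE_REFERENCE, _seq("T", "G", "C", "C")),
        ("s3b", "species3", ROLE_REFERENCE, _seq("T", "G", "C", "C")),
    ]
    return BarcodeSet.from_records(rows)
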