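"""Standard genetic code and the bicodon universe.

A bicodon is an ordered pair of adjacent in-frame codons; the first occupies
the ribosomal P-site, the second the A-site.  The universe of scored bicodons
is every sense P-site codon combined with every A-site codon (61 x 64 = 3904):
sense:stop pairs occur at the end of every CDS and are kept, while stop:sense
and stop:stop pairs cannot occur inside a valid CDS and are excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic order.
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)
)
CODON_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Symbol used for the stop "amino acid" in dipeptide labels.
STOP_SYMBOL = "*"


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code: 61 sense codons, 3 stops, 20 amino acids."""

    forward: dict[str, str]            # sense codon -> one-letter amino acid
    stop_codons: frozenset[str]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if c in self.forward)

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid, or ``*`` for a stop codon."""
        if codon in self.stop_codons:
            return STOP_SYMBOL
        return self.forward[codon]

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Synonymous codons of one amino acid (``*`` gives the stops)."""
        if aa == STOP_SYMBOL:
            return tuple(sorted(self.stop_codons))
        out = tuple(c for c in CODONS if self.forward.get(c) == aa)
        if not out:
            raise KeyError(f"unknown amino acid: {aa!r}")
        return out

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.forward.values())))


def standard_code() -> CodonTable:
    """The standard (NCBI table 1) genetic code."""
    t = _BioCodonTable.unambiguous_dna_by_id[1]
    forward = {c: aa for c, aa in t.forward_table.items() if set(c) <= set(NUCLEOTIDES)}
    table = CodonTable(forward=forward, stop_codons=frozenset(t.stop_codons))
    assert len(table.sense_codons) == 61 and len(table.stop_codons) == 3
    return table


@dataclass(frozen=True)
class BicodonIndex:
    """Ordered universe of the 3904 scored bicodons with fast lookups.

    Ordering is lexicographic: P-site sense codons in alphabetical order, each
    combined with all 64 A-site codons in alphabetical order.
    """

    table: CodonTable
    bicodons: tuple[str, ...]
    lookup: dict[str, int]
    #: per-bicodon index of the P-site codon into :data:`CODONS`
    p64: np.ndarray = field(repr=False)
    #: per-bicodon index of the A-site codon into :data:`CODONS`
    a64: np.ndarray = field(repr=False)
    #: per-bicodon dipeptide label, e.g. ``"KK"`` or ``"M*"``
    dipeptides: tuple[str, ...] = field(repr=False)
    #: rank of each sense codon among the 61 (stop codons -> -1), length 64
    sense_rank: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.bicodons)

    def __contains__(self, bicodon: str) -> bool:
        return bicodon in self.lookup


def enumerate_bicodons(table: CodonTable | None = None) -> BicodonIndex:
    """Enumerate the 61 x 64 = 3904 bicodon universe in deterministic order."""
    table = table or standard_code()
    sense = table.sense_codons
    sense_rank = np.full(64, -1, dtype=np.int64)
    for r, c in enumerate(sense):
        sense_rank[CODON_TO_INDEX[c]] = r

    bicodons = tuple(p + a for p in sense for a in CODONS)
    lookup = {b: i for i, b in enumerate(bicodons)}
    p64 = np.array([CODON_TO_INDEX[b[:3]] for b in bicodons], dtype=np.int64)
    a64 = np.array([CODON_TO_INDEX[b[3:]] for b in bicodons], dtype=np.int64)
    dipeptides = tuple(
        table.amino_acid(b[:3]) + table.amino_acid(b[3:]) for b in bicodons
    )
    return BicodonIndex(
        table=table,
        bicodons=bicodons,
        lookup=lookup,
        p64=p64,
        a64=a64,
        dipeptides=dipeptides,
        sense_rank=sense_rank,
    )
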