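"""Codon and bicodon counting over a sequence sample, plus synonymous groups.

Codons are read in frame 0; bicodons are every overlapping adjacent pair
(positions t, t+1), including each sequence's final sense:stop pair.  Counts
are additive over sequences.  Synonymous groups collect the bicodons encoding
one dipeptide (the three stop codons act as a single STOP symbol, so an
aa:STOP group has q = codons(aa) * 3 members); the groups partition the 3904
bicodon universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codes import CODON_TO_INDEX, BicodonIndex
from .sequence_io import CodingSequence, validate_cds


@dataclass
class SampleCounts:
    """Codon vector f (64), bicodon vector o (3904) and their totals."""

    f: np.ndarray
    o: np.ndarray
    n_tot: int
    n_p: int

    @classmethod
    def zeros(cls) -> "SampleCounts":
        return cls(
            f=np.zeros(64, dtype=np.int64),
            o=np.zeros(3904, dtype=np.int64),
            n_tot=0,
            n_p=0,
        )


@dataclass
class SynonymousGroup:
    """All bicodons encoding one amino-acid pair."""

    dipeptide: str
    members: np.ndarray           # indices into the bicodon universe
    q_ap: int
    n_ap_l: int = 0
    n_ap_h: int = 0


def encode_codons(seq: CodingSequence) -> np.ndarray:
    """Codon index array (into the 64 lexicographic codons) for one CDS."""
    return np.array([CODON_TO_INDEX[c] for c in seq.codons()], dtype=np.int64)


def counts_from_codes(
    codes: Sequence[np.ndarray] | np.ndarray,
    index: BicodonIndex,
    boundaries: np.ndarray | None = None,
) -> SampleCounts:
    """Count codons/bicodons from codon-index arrays.

    ``codes`` is either a list of per-sequence arrays or one concatenated
    array with ``boundaries`` giving each sequence's start offset.  Pairs
    never span sequence boundaries; pairs whose P-site codon is a stop are not
    part of the universe and are not counted.
    """
    if boundaries is None:
        seq_list = list(codes)
        lens = np.array([len(c) for c in seq_list], dtype=np.int64)
        concat = np.concatenate(seq_list) if seq_list else np.empty(0, dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]]) if seq_list else np.empty(0, dtype=np.int64)
    else:
        concat = np.asarray(codes)
        starts = np.asarray(boundaries)
    f = np.bincount(concat, minlength=64).astype(np.int64)
    n_tot = int(concat.size)
    if concat.size < 2:
        return SampleCounts(f=f, o=np.zeros(3904, dtype=np.int64), n_tot=n_tot, n_p=0)
    p = concat[:-1]
    a = concat[1:]
    pair_pos = np.ones(concat.size - 1, dtype=bool)
    # a pair at position t spans a boundary iff t+1 is a sequence start
    inner_starts = starts[1:] if starts.size else np.empty(0, dtype=np.int64)
    pair_pos[inner_starts - 1] = False
    n_p = int(pair_pos.sum())
    rank = index.sense_rank[p]
    valid = pair_pos & (rank >= 0)
    o = np.bincount(rank[valid] * 64 + a[valid], minlength=3904).astype(np.int64)
    return SampleCounts(f=f, o=o, n_tot=n_tot, n_p=n_p)


def count_sample(
    seqs: Iterable[CodingSequence],
    index: BicodonIndex,
    validate: bool = True,
) -> SampleCounts:
    """Count codons and overlapping bicodons over a sample of sequences."""
    code_arrays = []
    for s in seqs:
        if validate:
            validate_cds(s.id, s.nt, policy="strict")
        code_arrays.append(encode_codons(s))
    return counts_from_codes(code_arrays, index)


def build_groups(
    index: BicodonIndex,
    counts_l: SampleCounts | None = None,
    counts_h: SampleCounts | None = None,
) -> list[SynonymousGroup]:
    """Partition the bicodon universe into synonymous (dipeptide) groups."""
    by_dipeptide: dict[str, list[int]] = {}
    for i, dp in enumerate(index.dipeptides):
        by_dipeptide.setdefault(dp, []).append(i)
    groups: list[SynonymousGroup] = []
    for dp in sorted(by_dipeptide):
        members = np.array(by_dipeptide[dp], dtype=np.int64)
        g = SynonymousGroup(dipeptide=dp, members=members, q_ap=len(members))
        if counts_l is not None:
            g.n_ap_l = int(counts_l.o[members].sum())
        if counts_h is not None:
            g.n_ap_h = int(counts_h.o[members].sum())
        groups.append(g)
    return groups


def group_arrays(index: BicodonIndex, groups: Sequence[SynonymousGroup]) -> tuple[np.ndarray, np.ndarray]:
    """Per-bicodon group id and per-group q, aligned with ``groups`` order."""
    gid = np.empty(len(index), dtype=np.int64)
    q = np.empty(len(groups), dtype=np.int64)
    for k, g in enumerate(groups):
        gid[g.members] = k
        q[k] = g.q_ap
    return gid, q


def counts_frame(
    index: BicodonIndex,
    counts_l: SampleCounts,
    counts_h: SampleCounts,
) -> pd.DataFrame:
    """Per-bicodon count table: dipeptide, bicodon, o_L, o_H."""
    return pd.DataFrame(
        {
            "dipeptide": list(index.dipeptides),
            "bicodon": list(index.bicodons),
            "o_L": counts_l.o,
            "o_H": counts_h.o,
        }
    )


def write_counts_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        return pd.read_csv(fh, sep="\t", names=header)
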