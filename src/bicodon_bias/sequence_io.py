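"""Reading, validating and writing coding sequences and abundance tables.

Coding sequences arrive as nucleotide FASTA (one record per protein).  Protein
abundances arrive as a four-column whitespace/tab-separated table: internal
index, identifier, abundance (e.g. ppm), and coding-sequence length in
nucleotides.  All tabular outputs are TSV with a single ``#``-prefixed header
line so they round-trip losslessly.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .codes import standard_code

log = logging.getLogger(__name__)

_STOPS = standard_code().stop_codons
_VALID_NT = re.compile(r"^[ACGT]*$")

Policy = Literal["strict", "lenient"]


class ValidationError(ValueError):
    """A sequence or table row violating the CDS/abundance contracts."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence.

    ``nt`` is the normalized nucleotide string (uppercase DNA, U mapped to T);
    ``n_codons`` counts every in-frame triplet including the terminal stop.
    """

    id: str
    nt: str
    abundance: float | None = None

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3

    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]

    def with_abundance(self, abundance: float) -> "CodingSequence":
        return replace(self, abundance=abundance)


@dataclass(frozen=True)
class AbundanceRecord:
    index: int
    id: str
    abundance: float
    cds_length: int  # nucleotides


def normalize_nt(raw: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def validate_cds(seq_id: str, nt: str, policy: Policy = "strict") -> None:
    """Check the CodingSequence invariants, raising :class:`ValidationError`.

    Under either policy the length must be a positive multiple of 3 and the
    alphabet restricted to ACGT.  The strict policy additionally requires a
    terminal stop codon and forbids internal stops (the shuffle null keeps the
    terminal stop fixed, so analysed sequences must carry one).
    """
    if len(nt) == 0 or len(nt) % 3 != 0:
        raise ValidationError(f"{seq_id}: length {len(nt)} is not a positive multiple of 3")
    if not _VALID_NT.match(nt):
        bad = sorted(set(nt) - set("ACGT"))
        raise ValidationError(f"{seq_id}: non-ACGT characters {bad}")
    if policy == "strict":
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons[-1] not in _STOPS:
            raise ValidationError(f"{seq_id}: no terminal stop codon (ends {codons[-1]})")
        internal = [i + 1 for i, c in enumerate(codons[:-1]) if c in _STOPS]
        if internal:
            raise ValidationError(f"{seq_id}: internal stop codon at position {internal[0]}")


def read_cds_fasta(path: str | Path, policy: Policy = "strict") -> list[CodingSequence]:
    """Read and validate coding sequences from (optionally gzipped) FASTA.

    Strict policy aborts on the first invalid record, naming it; lenient
    policy skips invalid records with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out: list[CodingSequence] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            nt = normalize_nt(str(rec.seq))
            try:
                validate_cds(rec.id, nt, policy)
            except ValidationError as exc:
                if policy == "strict":
                    raise
                log.warning("skipping invalid record: %s", exc)
                continue
            out.append(CodingSequence(id=rec.id, nt=nt))
    return out


def write_cds_fasta(seqs: Iterable[CodingSequence], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.nt), width):
                fh.write(s.nt[i : i + width] + "\n")


def read_abundance_table(path: str | Path, policy: Policy = "strict") -> list[AbundanceRecord]:
    """Parse a four-column abundance table (index, id, abundance, CDS length).

    A header line is tolerated (first non-comment line whose third field is
    not numeric).  Malformed data rows abort under strict policy with the row
    number, and are skipped with a warning under lenient policy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[AbundanceRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    data_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        err: str | None = None
        if len(fields) < 4:
            err = f"row {lineno}: expected >= 4 columns, got {len(fields)}"
        else:
            try:
                abundance = float(fields[2])
                cds_length = int(fields[3])
                index = int(fields[0])
            except ValueError:
                err = f"row {lineno}: non-numeric field in {fields[:4]}"
            else:
                if abundance < 0:
                    err = f"row {lineno}: negative abundance {abundance}"
        if err is not None:
            # allow one header line before any data row
            if not data_seen and not records:
                log.debug("treating line %d as header: %r", lineno, line)
                continue
            if policy == "strict":
                raise ValidationError(err)
            log.warning("skipping %s", err)
            continue
        data_seen = True
        records.append(AbundanceRecord(index=index, id=fields[1], abundance=abundance, cds_length=cds_length))
    if not records:
        raise ValidationError(f"{path}: no abundance records parsed")
    return records


def write_abundance_table(records: Iterable[AbundanceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#index\tid\tabundance\tcds_length\n")
        for r in records:
            fh.write(f"{r.index}\t{r.id}\t{r.abundance:.6g}\t{r.cds_length}\n")


def join_sequences_abundance(
    seqs: Iterable[CodingSequence],
    table: Iterable[AbundanceRecord],
    strip_versions: bool = False,
) -> list[CodingSequence]:
    """Attach abundances to sequences by exact ID match.

    ``strip_versions`` removes a trailing ``.N`` version suffix from both ID
    schemes before matching (Ensembl-style versioned IDs).  Unmatched IDs on
    either side are reported via warnings; a total mismatch is an error.
    """

    def key(s: str) -> str:
        return re.sub(r"\.\d+$", "", s) if strip_versions else s

    by_id: dict[str, AbundanceRecord] = {}
    for rec in table:
        k = key(rec.id)
        if k in by_id:
            raise ValidationError(f"duplicate ID in abundance table: {rec.id}")
        by_id[k] = rec

    joined: list[CodingSequence] = []
    unmatched_seqs: list[str] = []
    matched_keys: set[str] = set()
    for s in seqs:
        k = key(s.id)
        rec = by_id.get(k)
        if rec is None:
            unmatched_seqs.append(s.id)
            continue
        if rec.cds_length != len(s.nt):
            log.warning(
                "%s: table cds_length %d != sequence length %d", s.id, rec.cds_length, len(s.nt)
            )
        matched_keys.add(k)
        joined.append(s.with_abundance(rec.abundance))
    unmatched_table = [r.id for k, r in by_id.items() if k not in matched_keys]
    if unmatched_seqs:
        log.warning("%d sequences without abundance (e.g. %s)", len(unmatched_seqs), unmatched_seqs[:3])
    if unmatched_table:
        log.warning("%d abundance rows without sequence (e.g. %s)", len(unmatched_table), unmatched_table[:3])
    if not joined:
        raise ValidationError("zero ID matches between sequences and abundance table (ID-scheme mismatch?)")
    return joined
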