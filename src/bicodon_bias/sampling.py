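"""Selection of length-matched low/high abundance sequence samples.

Candidates are ordered by abundance and walked from one extreme; each
candidate of length ``l`` is accepted with probability
``exp(-(l - l_o)**2 / (2 * sigma))`` against a fresh uniform draw, until
``n_select`` records are accepted.  With ``sigma`` equal to the variance of
the target length distribution this is a Gaussian weight in standardized
length, which downweights candidates whose length is far from the target mean
and thereby pulls the length distributions of the two opposite-extreme
samples toward each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .sequence_io import AbundanceRecord

log = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    n_select: int = 500
    direction: Literal["low", "high"] = "low"
    l_o: float | None = None     # target mean length; None -> fit from candidates
    sigma: float | None = None   # variance-role spread; None -> candidate length variance
    seed: int = 0
    max_passes: int = 100
    length_units: Literal["nt", "codons"] = "nt"

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


def acceptance_probability(length: float, l_o: float, sigma: float) -> float:
    """The Gaussian acceptance weight exp(-(l - l_o)^2 / (2 sigma))."""
    return math.exp(-((length - l_o) ** 2) / (2.0 * sigma))


def dedupe_isoforms(
    records: Sequence[AbundanceRecord],
    id_to_gene: Mapping[str, str] | None = None,
) -> list[AbundanceRecord]:
    """Keep one isoform per gene: highest abundance, ties to the smallest ID.

    ``id_to_gene`` maps record IDs to gene identifiers; ``None`` means the
    identity mapping (every record its own gene, input returned unchanged in
    original order).
    """
    if id_to_gene is None:
        id_to_gene = {r.id: r.id for r in records}
    best: dict[str, AbundanceRecord] = {}
    order: list[str] = []
    for r in records:
        gene = id_to_gene[r.id]
        cur = best.get(gene)
        if cur is None:
            best[gene] = r
            order.append(gene)
        elif (r.abundance, cur.id) > (cur.abundance, r.id):
            # higher abundance wins; equal abundance -> lexicographically
            # smaller ID wins (cur stays only if cur.id < r.id)
            best[gene] = r
    return [best[g] for g in order]


def select_length_matched(
    records: Sequence[AbundanceRecord],
    config: SamplerConfig,
) -> list[AbundanceRecord]:
    """Rejection-sample ``n_select`` records from one abundance extreme.

    Records are sorted by abundance ascending (ties by ID for determinism);
    ``direction="low"`` walks from the least abundant end, ``"high"`` from the
    most abundant.  Unaccepted records are revisited with fresh uniform draws
    for up to ``max_passes`` passes; a persistent shortfall raises
    :class:`SamplingError` advising a larger sigma.
    """
    if len(records) < config.n_select:
        raise SamplingError(
            f"only {len(records)} candidates for n_select={config.n_select}"
        )
    scale = 3.0 if config.length_units == "codons" else 1.0
    lengths = {r.id: r.cds_length / scale for r in records}
    pooled = np.array(list(lengths.values()), dtype=float)
    l_o = float(pooled.mean()) if config.l_o is None else config.l_o
    sigma = float(pooled.var()) if config.sigma is None else config.sigma
    if sigma <= 0:
        raise SamplingError("degenerate length distribution: sigma <= 0")

    walk = sorted(records, key=lambda r: (r.abundance, r.id))
    if config.direction == "high":
        walk = walk[::-1]

    rng = np.random.default_rng(config.seed)
    accepted: list[AbundanceRecord] = []
    remaining = list(walk)
    for _ in range(config.max_passes):
        still: list[AbundanceRecord] = []
        for rec in remaining:
            if acceptance_probability(lengths[rec.id], l_o, sigma) > rng.random():
                accepted.append(rec)
                if len(accepted) == config.n_select:
                    return accepted
            else:
                still.append(rec)
        remaining = still
    raise SamplingError(
        f"accepted only {len(accepted)}/{config.n_select} records after "
        f"{config.max_passes} passes; consider a larger sigma"
    )
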