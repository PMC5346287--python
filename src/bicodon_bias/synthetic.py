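"""Synthetic proteome generator with plantable codon-pair couplings.

The generator emulates the statistical structure the analysis assumes about
real proteome data: a right-skewed (lognormal) protein-abundance
distribution, a negative correlation between abundance and coding-sequence
length, expression-class-dependent single-codon usage profiles, and --
optionally -- first-order codon-pair couplings of tunable strength.  A
coupling multiplies the within-amino-acid weight of an A-site codon whenever
it follows a given P-site codon, then renormalizes among the synonymous
codons, so it biases bicodon usage while leaving the amino-acid sequence
distribution untouched.  Because the planted conditional distributions are
known in closed form (:func:`expected_pair_frequency`), every downstream
statistic can be verified by parameter recovery.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .codes import CodonTable, standard_code
from .sequence_io import AbundanceRecord, CodingSequence

GeneClass = Literal["low", "high"]

#: Average amino-acid composition of a eukaryotic proteome (UniProt-style
#: frequencies, normalized).  Used as the default residue distribution.
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: Stop-codon usage roughly as in yeast.
DEFAULT_STOP_WEIGHTS: dict[str, float] = {"TAA": 0.47, "TAG": 0.23, "TGA": 0.30}


@dataclass(frozen=True)
class Coupling:
    """Multiply the weight of ``a_site`` by ``multiplier`` after ``p_site``."""

    p_site: str
    a_site: str
    multiplier: float
    gene_class: Literal["low", "high", "both"] = "both"

    def applies_to(self, cls: GeneClass) -> bool:
        return self.gene_class in ("both", cls)


@dataclass(frozen=True)
class LengthModel:
    """Lognormal codon count: log(n_codons) ~ Normal(log_mean, log_sd), with
    correlation ``rho`` (<= 0) between log-length and log-abundance."""

    log_mean: float = 6.0     # exp(6) ~ 403 codons
    log_sd: float = 0.5
    rho: float = -0.2


@dataclass(frozen=True)
class AbundanceModel:
    """Lognormal abundance in ppm: log(a) ~ Normal(log_mean, log_sd)."""

    log_mean: float = 1.5
    log_sd: float = 2.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 2000
    seed: int = 0
    length_model: LengthModel = field(default_factory=LengthModel)
    abundance_model: AbundanceModel = field(default_factory=AbundanceModel)
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    codon_profile_low: Mapping[str, Mapping[str, float]] | None = None
    codon_profile_high: Mapping[str, Mapping[str, float]] | None = None
    couplings: tuple[Coupling, ...] = ()
    stop_codon_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOP_WEIGHTS)
    )

    def profile(self, cls: GeneClass, table: CodonTable) -> dict[str, dict[str, float]]:
        prof = self.codon_profile_low if cls == "low" else self.codon_profile_high
        if prof is None:
            prof = uniform_profile(table) if cls == "low" else biased_profile(table)
        return {aa: dict(row) for aa, row in prof.items()}


def uniform_profile(table: CodonTable | None = None) -> dict[str, dict[str, float]]:
    """Uniform codon weights within every amino acid."""
    table = table or standard_code()
    return {
        aa: {c: 1.0 / len(table.codons_for(aa)) for c in table.codons_for(aa)}
        for aa in table.amino_acids
    }


def biased_profile(table: CodonTable | None = None, base: float = 2.0) -> dict[str, dict[str, float]]:
    """Geometrically biased codon weights (w_k proportional to base**-k over an
    amino acid's codons in alphabetical order), emulating the stronger codon
    usage bias of highly expressed genes."""
    table = table or standard_code()
    out: dict[str, dict[str, float]] = {}
    for aa in table.amino_acids:
        codons = table.codons_for(aa)
        w = np.array([base ** (-k) for k in range(len(codons))])
        w /= w.sum()
        out[aa] = dict(zip(codons, w))
    return out


def _validate_profile(profile: Mapping[str, Mapping[str, float]], table: CodonTable) -> None:
    for aa in table.amino_acids:
        row = profile.get(aa)
        if row is None:
            raise ValueError(f"profile missing amino acid {aa}")
        total = sum(row.values())
        if any(w < 0 for w in row.values()) or total <= 0:
            raise ValueError(f"degenerate profile row for {aa}: weights {row}")
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"profile row for {aa} sums to {total}, expected 1")
        for c in row:
            if table.amino_acid(c) != aa:
                raise ValueError(f"codon {c} does not encode {aa}")


def expected_pair_frequency(
    config: GeneratorConfig,
    prev: str,
    aa: str,
    gene_class: GeneClass = "low",
    table: CodonTable | None = None,
) -> dict[str, float]:
    """Exact conditional codon distribution used inside :func:`generate_proteome`.

    Returns, for a gene of ``gene_class`` whose previous codon is ``prev``,
    the renormalized distribution over the synonymous codons of ``aa``:
    profile weight times any applicable coupling multiplier.  This is the
    closed-form oracle against which planted effects are recovered.
    """
    table = table or standard_code()
    if prev not in table.forward:
        raise ValueError(f"previous codon must be a sense codon, got {prev!r}")
    profile = config.profile(gene_class, table)
    if aa not in profile:
        raise KeyError(f"unknown amino acid: {aa!r}")
    weights = dict(profile[aa])
    for cp in config.couplings:
        if cp.p_site == prev and cp.a_site in weights and cp.applies_to(gene_class):
            weights[cp.a_site] *= cp.multiplier
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


class _ClassSampler:
    """Cumulative-weight tables for one expression class, couplings applied."""

    def __init__(self, config: GeneratorConfig, cls: GeneClass, table: CodonTable):
        profile = config.profile(cls, table)
        _validate_profile(profile, table)
        self.base: dict[str, tuple[list[str], list[float]]] = {}
        for aa, row in profile.items():
            codons = list(row)
            cum = np.cumsum([row[c] for c in codons])
            self.base[aa] = (codons, list(cum / cum[-1]))
        # adjusted tables only for (prev, aa) combinations a coupling touches
        self.adjusted: dict[tuple[str, str], tuple[list[str], list[float]]] = {}
        prevs = {cp.p_site for cp in config.couplings if cp.applies_to(cls)}
        for prev in prevs:
            for aa in profile:
                dist = expected_pair_frequency(config, prev, aa, cls, table)
                codons = list(dist)
                cum = np.cumsum([dist[c] for c in codons])
                self.adjusted[(prev, aa)] = (codons, list(cum / cum[-1]))
        self.coupled_prevs = prevs

    def draw(self, prev: str | None, aa: str, u: float) -> str:
        if prev is not None and prev in self.coupled_prevs:
            codons, cum = self.adjusted[(prev, aa)]
        else:
            codons, cum = self.base[aa]
        return codons[bisect.bisect_left(cum, u)]


def generate_proteome(
    config: GeneratorConfig,
) -> tuple[list[CodingSequence], list[AbundanceRecord]]:
    """Generate a synthetic proteome (CDS set plus abundance table).

    Per gene: abundance is drawn lognormally; the codon count is drawn so
    log-length and log-abundance correlate at ``rho``; the residue sequence is
    i.i.d. from ``aa_frequencies`` with the first residue forced to Met; codons
    follow the first-order chain of :func:`expected_pair_frequency` using the
    low profile for genes below the median abundance and the high profile
    above; a stop codon closes the sequence.  Deterministic given the seed.
    """
    if config.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    table = standard_code()
    samplers = {
        "low": _ClassSampler(config, "low", table),
        "high": _ClassSampler(config, "high", table),
    }
    stop_codons = list(config.stop_codon_weights)
    stop_w = np.array([config.stop_codon_weights[c] for c in stop_codons], dtype=float)
    if (stop_w < 0).any() or stop_w.sum() <= 0:
        raise ValueError("degenerate stop codon weights")
    stop_cum = list(np.cumsum(stop_w) / stop_w.sum())

    aas = sorted(config.aa_frequencies)
    aa_w = np.array([config.aa_frequencies[a] for a in aas], dtype=float)
    if (aa_w < 0).any() or aa_w.sum() <= 0:
        raise ValueError("degenerate amino-acid frequencies")
    aa_p = aa_w / aa_w.sum()

    rng = np.random.default_rng(config.seed)
    am, lm = config.abundance_model, config.length_model
    if lm.rho > 0:
        raise ValueError("length-abundance correlation rho must be <= 0")
    z_a = rng.standard_normal(config.n_genes)
    z_l = lm.rho * z_a + math.sqrt(1.0 - lm.rho**2) * rng.standard_normal(config.n_genes)
    abundance = np.exp(am.log_mean + am.log_sd * z_a)
    n_codons = np.maximum(2, np.round(np.exp(lm.log_mean + lm.log_sd * z_l))).astype(int)
    median = float(np.median(abundance))

    n_digits = len(str(config.n_genes))
    seqs: list[CodingSequence] = []
    records: list[AbundanceRecord] = []
    for g in range(config.n_genes):
        cls: GeneClass = "low" if abundance[g] < median else "high"
        sampler = samplers[cls]
        n = int(n_codons[g])
        aa_seq = ["M"] + list(rng.choice(aas, size=n - 1, p=aa_p))
        u = rng.random(n + 1)
        codons: list[str] = []
        prev: str | None = None
        for t, aa in enumerate(aa_seq):
            codon = sampler.draw(prev, aa, u[t])
            codons.append(codon)
            prev = codon
        codons.append(stop_codons[bisect.bisect_left(stop_cum, u[n])])
        gid = f"SYN{g + 1:0{n_digits}d}"
        nt = "".join(codons)
        seqs.append(CodingSequence(id=gid, nt=nt, abundance=float(abundance[g])))
        records.append(
            AbundanceRecord(index=g + 1, id=gid, abundance=float(abundance[g]), cds_length=len(nt))
        )
    return seqs, records


def gene_classes(records: Sequence[AbundanceRecord]) -> dict[str, GeneClass]:
    """Median-split expression class per gene, as used by the generator."""
    med = float(np.median([r.abundance for r in records]))
    return {r.id: ("low" if r.abundance < med else "high") for r in records}
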