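"""Codon-shuffling null for the residual scores, and bicodon classification.

Shuffling the order of codons within each sequence (the terminal stop stays
put) destroys codon-pair correlations while preserving every single-codon
count, so the residual score chi2 recomputed on shuffled replicates gives an
empirical null for "how much pair structure arises from codon usage alone".
The observed chi2 is then expressed in null standard deviations:

    z = (chi2 - <chi2>_ran) / SD_ran(chi2).

Every bicodon falls into one of four categories: significantly biased toward
low-abundance sequences and unexplained by codon usage (z at or above the
threshold), the high-abundance mirror image, significantly biased but
explained, or not significantly biased at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .codes import BicodonIndex
from .counting import SampleCounts, SynonymousGroup, counts_from_codes, encode_codons
from .sequence_io import CodingSequence, ValidationError
from .stats import chi2_for_sample, normalize_expected, residual_score, expected_counts

log = logging.getLogger(__name__)

_STOP_CODES = frozenset({"TAA", "TAG", "TGA"})

CATEGORIES = ("low_unexplained", "high_unexplained", "explained_biased", "unbiased")
WITHHELD = "withheld"

CombineRule = Literal["max", "sum"]


@dataclass
class NullMoments:
    """Per-bicodon mean and SD of chi2 across shuffle replicates."""

    mean: np.ndarray
    sd: np.ndarray
    n_reps: int
    seed: int


def shuffle_codons(
    seq: CodingSequence, rng: np.random.Generator, require_stop: bool = True
) -> CodingSequence:
    """Uniformly permute a sequence's codons, keeping the terminal stop fixed."""
    codons = seq.codons()
    if codons[-1] not in _STOP_CODES:
        if require_stop:
            raise ValidationError(f"{seq.id}: cannot shuffle, no terminal stop codon")
        body, tail = codons, []
    else:
        body, tail = codons[:-1], [codons[-1]]
    perm = rng.permutation(len(body))
    shuffled = [body[i] for i in perm] + tail
    return CodingSequence(id=seq.id, nt="".join(shuffled), abundance=seq.abundance)


def _shuffled_counts(
    concat: np.ndarray,
    starts: np.ndarray,
    seg_id: np.ndarray,
    last_pos: np.ndarray,
    index: BicodonIndex,
    rng: np.random.Generator,
) -> SampleCounts:
    """One shuffle replicate: permute within segments, terminal codon fixed.

    Each position gets the key segment*2 + Uniform(0,1); the terminal codon
    of each segment gets segment*2 + 1.5, above any uniform draw.  A single
    argsort then keeps segments contiguous and in order, permutes each
    segment body independently and uniformly, and leaves every terminal stop
    in place.
    """
    keys = 2.0 * seg_id + rng.random(concat.size)
    keys[last_pos] = 2.0 * seg_id[last_pos] + 1.5
    order = np.argsort(keys)
    return counts_from_codes(concat[order], index, boundaries=starts)


def null_moments(
    seqs: Sequence[CodingSequence],
    index: BicodonIndex,
    groups: Sequence[SynonymousGroup],
    n_reps: int = 200,
    seed: int = 0,
) -> NullMoments:
    """Mean and SD of per-bicodon chi2 over codon-shuffle replicates.

    e is computed once (shuffling preserves the codon count vector f) but the
    group rescaling to e_hat and the residual chi2 are recomputed inside every
    replicate, since both depend on the replicate's bicodon counts.  Each
    replicate draws from its own stream spawned from the master seed, so the
    set of replicates is deterministic given (seqs, n_reps, seed).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    code_arrays = [encode_codons(s) for s in seqs]
    for s, c in zip(seqs, code_arrays):
        if s.codons()[-1] not in _STOP_CODES:
            raise ValidationError(f"{s.id}: cannot shuffle, no terminal stop codon")
    lens = np.array([c.size for c in code_arrays], dtype=np.int64)
    concat = np.concatenate(code_arrays)
    ends = np.cumsum(lens)
    starts = ends - lens
    seg_id = np.repeat(np.arange(len(lens)), lens)
    last_pos = ends - 1

    base = counts_from_codes(concat, index, boundaries=starts)
    e = expected_counts(base, index)

    total = np.zeros(len(index))
    total_sq = np.zeros(len(index))
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for child in streams:
        rng = np.random.Generator(np.random.PCG64(child))
        rep = _shuffled_counts(concat, starts, seg_id, last_pos, index, rng)
        ehat = normalize_expected(e, rep.o, groups, index)
        chi2 = residual_score(rep.o, ehat)
        total += chi2
        total_sq += chi2**2
    mean = total / n_reps
    var = np.maximum(total_sq / n_reps - mean**2, 0.0) * n_reps / (n_reps - 1)
    return NullMoments(mean=mean, sd=np.sqrt(var), n_reps=n_reps, seed=seed)


def standardize_residuals(chi2: np.ndarray, moments: NullMoments) -> np.ndarray:
    """z = (chi2 - null mean) / null SD.

    Degenerate bicodons with SD = 0 give z = 0 when chi2 equals the null mean
    and NaN (an undefined sentinel, excluded from classification) otherwise.
    """
    chi2 = np.asarray(chi2, dtype=float)
    sd_ok = moments.sd > 0
    z = np.full(chi2.shape, np.nan)
    z[sd_ok] = (chi2[sd_ok] - moments.mean[sd_ok]) / moments.sd[sd_ok]
    exact = (~sd_ok) & (chi2 == moments.mean)
    z[exact] = 0.0
    n_undef = int(np.isnan(z).sum())
    if n_undef:
        log.warning("%d bicodons with undefined null z (SD = 0, chi2 != mean)", n_undef)
    return z


def combined_z(
    z_l: np.ndarray,
    z_h: np.ndarray,
    rule: CombineRule = "max",
    moments_l: NullMoments | None = None,
    moments_h: NullMoments | None = None,
    chi2_l: np.ndarray | None = None,
    chi2_h: np.ndarray | None = None,
) -> np.ndarray:
    """Combine the per-sample null deviations into one score.

    ``max`` takes the larger of the two z values (a per-axis reading of the
    3-SD quadrant rule).  ``sum`` standardizes the summed residual
    chi2_L + chi2_H against its own null moments (means add; variances add
    because the two samples are shuffled independently), which requires the
    raw chi2 vectors and both moment sets.
    """
    if rule == "max":
        return np.fmax(z_l, z_h)  # fmax ignores NaN on one side only
    if rule != "sum":
        raise ValueError(f"unknown combine rule: {rule!r}")
    if any(x is None for x in (moments_l, moments_h, chi2_l, chi2_h)):
        raise ValueError("sum rule needs chi2 vectors and both null moment sets")
    mean = moments_l.mean + moments_h.mean
    sd = np.sqrt(moments_l.sd**2 + moments_h.sd**2)
    total = np.asarray(chi2_l, dtype=float) + np.asarray(chi2_h, dtype=float)
    z = np.full(total.shape, np.nan)
    ok = sd > 0
    z[ok] = (total[ok] - mean[ok]) / sd[ok]
    z[(~ok) & (total == mean)] = 0.0
    return z


def classify_bicodons(
    p_value: np.ndarray,
    pi: np.ndarray,
    z_l: np.ndarray,
    z_h: np.ndarray,
    alpha: float = 0.01,
    z_threshold: float = 3.0,
    combine: CombineRule = "max",
    **combine_kwargs,
) -> pd.Series:
    """Four-way classification of every bicodon.

    unbiased if p >= alpha; otherwise low_unexplained / high_unexplained by
    the sign of pi when the combined null deviation reaches ``z_threshold``;
    otherwise explained_biased.  Significant bicodons whose z is undefined are
    withheld and logged.
    """
    p_value = np.asarray(p_value, dtype=float)
    pi = np.asarray(pi, dtype=float)
    score = combined_z(np.asarray(z_l), np.asarray(z_h), combine, **combine_kwargs)

    cat = np.full(p_value.shape, "unbiased", dtype=object)
    sig = p_value < alpha
    undef = sig & np.isnan(score)
    if undef.any():
        log.warning("%d significant bicodons withheld (undefined z)", int(undef.sum()))
    cat[sig] = "explained_biased"
    unexplained = sig & ~undef & (score >= z_threshold)
    cat[unexplained & (pi > 0)] = "low_unexplained"
    cat[unexplained & (pi <= 0)] = "high_unexplained"
    cat[undef] = WITHHELD
    return pd.Series(
        pd.Categorical(cat, categories=list(CATEGORIES) + [WITHHELD]), name="category"
    )
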