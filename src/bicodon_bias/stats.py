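"""Per-bicodon bias statistics: RSBU, pause propensity, Fisher p, residuals.

The pause propensity of bicodon ij is

    pi_ij = RSBU_ij^L - RSBU_ij^H,

the difference in relative synonymous bicodon usage between the low- and
high-abundance samples; positive values mark bicodons preferentially used in
lowly abundant proteins.  RSBU is the bicodon analogue of RSCU: the bicodon's
count scaled by its synonymous-group size q over the group total, so uniform
usage within a group gives RSBU = 1 for every member.

The residual score asks a different question: whether a bicodon's frequency
within one sample deviates from what its single-codon frequencies predict.
The raw expectation e_ij = f_i f_j N_p / N_tot^2 is rescaled within each
synonymous group so group totals match the observation (removing amino-acid
pair nonrandomness), and chi2 = (o - e_hat)^2 / e_hat measures the remaining
deviation.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .codes import BicodonIndex
from .counting import SampleCounts, SynonymousGroup, group_arrays
from .fisher import FactorialMode, fisher_many

log = logging.getLogger(__name__)

RsbuNormalization = Literal["per_sample", "pooled"]
FisherBackground = Literal["group", "sample"]

#: Sentinel for chi2 with zero expectation but non-zero observation.
CHI2_INF = np.inf


def compute_rsbu(
    counts: SampleCounts,
    groups: Sequence[SynonymousGroup],
    index: BicodonIndex,
    sample: Literal["L", "H"],
    normalization: RsbuNormalization = "per_sample",
) -> np.ndarray:
    """Relative synonymous bicodon usage for one sample.

    ``per_sample`` divides by the group total of the same sample (each group's
    RSBU then sums to q); ``pooled`` divides by the combined L+H group total,
    the literal single-N_ap reading.  Groups with a zero denominator yield
    RSBU = 0 for all members and are logged.
    """
    gid, q = group_arrays(index, groups)
    if normalization == "per_sample":
        totals = np.array(
            [g.n_ap_l if sample == "L" else g.n_ap_h for g in groups], dtype=float
        )
    else:
        totals = np.array([g.n_ap_l + g.n_ap_h for g in groups], dtype=float)
    empty = totals == 0
    if empty.any():
        log.debug(
            "%d synonymous groups empty in sample %s: %s",
            int(empty.sum()),
            sample,
            [groups[k].dipeptide for k in np.flatnonzero(empty)][:5],
        )
    safe = np.where(empty, 1.0, totals)
    rsbu = q[gid] * counts.o / safe[gid]
    rsbu[empty[gid]] = 0.0
    return rsbu


def compute_pause_propensity(rsbu_l: np.ndarray, rsbu_h: np.ndarray) -> np.ndarray:
    """pi = RSBU^L - RSBU^H, elementwise."""
    return np.asarray(rsbu_l) - np.asarray(rsbu_h)


def preference_sign(
    o_l: np.ndarray, o_h: np.ndarray, syn_l: np.ndarray, syn_h: np.ndarray
) -> np.ndarray:
    """S = +1 for low-abundance preference, -1 for high, 0 for a tie.

    Preference compares the within-group proportions o/syn of the two
    samples (empty groups count as proportion 0).
    """
    prop_l = np.divide(o_l, syn_l, out=np.zeros(len(o_l)), where=syn_l > 0)
    prop_h = np.divide(o_h, syn_h, out=np.zeros(len(o_h)), where=syn_h > 0)
    return np.sign(prop_l - prop_h).astype(np.int64)


def signed_logp(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """-S log10(p), oriented so low-abundance-preferring bicodons are positive.

    Ties (S = 0) and p = 1 give 0.  p = 0 is clamped to the smallest positive
    double with a warning.
    """
    p = np.asarray(p, dtype=float)
    if (p == 0).any():
        log.warning("%d p-values of exactly 0 clamped", int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    out = -np.asarray(sign, dtype=float) * np.log10(p)
    # -0.0 -> 0.0 for tidy output
    return out + 0.0


def expected_counts(counts: SampleCounts, index: BicodonIndex) -> np.ndarray:
    """Raw expected bicodon counts e_ij = f_i f_j N_p / N_tot^2.

    f runs over all 64 codons (stop codons occur at A-sites); the restriction
    to the 3904-bicodon universe happens through the index.
    """
    if counts.n_tot == 0:
        raise ValueError("empty sample: N_tot = 0")
    f = counts.f.astype(float)
    return f[index.p64] * f[index.a64] * counts.n_p / counts.n_tot**2


def normalize_expected(
    e: np.ndarray,
    o: np.ndarray,
    groups: Sequence[SynonymousGroup],
    index: BicodonIndex,
) -> np.ndarray:
    """Rescale e within each synonymous group so group sums match o.

    e_hat_ij = e_ij * (sum* o) / (sum* e) with sums over the bicodon's group;
    groups with sum* e = 0 yield e_hat = 0.
    """
    gid, _ = group_arrays(index, groups)
    n_groups = len(groups)
    sum_e = np.bincount(gid, weights=e, minlength=n_groups)
    sum_o = np.bincount(gid, weights=o.astype(float), minlength=n_groups)
    scale = np.divide(sum_o, sum_e, out=np.zeros(n_groups), where=sum_e > 0)
    return e * scale[gid]


def residual_score(o: np.ndarray, ehat: np.ndarray) -> np.ndarray:
    """chi2 = (o - e_hat)^2 / e_hat; 0/0 -> 0, positive/0 -> +inf (flagged)."""
    o = np.asarray(o, dtype=float)
    ehat = np.asarray(ehat, dtype=float)
    if (ehat < 0).any():
        raise ValueError("negative expected counts")
    chi2 = np.zeros_like(o)
    ok = ehat > 0
    chi2[ok] = (o[ok] - ehat[ok]) ** 2 / ehat[ok]
    undef = (~ok) & (o > 0)
    if undef.any():
        log.warning("%d bicodons observed with zero expectation (chi2 = inf)", int(undef.sum()))
        chi2[undef] = CHI2_INF
    return chi2


def chi2_for_sample(
    counts: SampleCounts,
    groups: Sequence[SynonymousGroup],
    index: BicodonIndex,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(e, e_hat, chi2) for one sample."""
    e = expected_counts(counts, index)
    ehat = normalize_expected(e, counts.o, groups, index)
    return e, ehat, residual_score(counts.o, ehat)


def compute_bicodon_stats(
    counts_l: SampleCounts,
    counts_h: SampleCounts,
    index: BicodonIndex,
    groups: Sequence[SynonymousGroup],
    *,
    rsbu_normalization: RsbuNormalization = "per_sample",
    factorial_mode: FactorialMode = "lgamma",
    fisher_background: FisherBackground = "group",
    benjamini_hochberg: bool = True,
) -> pd.DataFrame:
    """Assemble the full per-bicodon statistics table.

    One row per bicodon in universe order, with columns: dipeptide, bicodon,
    o_L, o_H, rsbu_L, rsbu_H, pi, p_value, S, signed_logp, e_L, e_H, ehat_L,
    ehat_H, chi2_L, chi2_H (and p_bh when ``benjamini_hochberg``).
    """
    gid, _ = group_arrays(index, groups)
    rsbu_l = compute_rsbu(counts_l, groups, index, "L", rsbu_normalization)
    rsbu_h = compute_rsbu(counts_h, groups, index, "H", rsbu_normalization)
    pi = compute_pause_propensity(rsbu_l, rsbu_h)

    if fisher_background == "group":
        syn_l = np.array([g.n_ap_l for g in groups], dtype=np.int64)[gid]
        syn_h = np.array([g.n_ap_h for g in groups], dtype=np.int64)[gid]
    else:
        syn_l = np.full(len(index), counts_l.n_p, dtype=np.int64)
        syn_h = np.full(len(index), counts_h.n_p, dtype=np.int64)
    p = fisher_many(counts_l.o, counts_h.o, syn_l, syn_h, factorial_mode)
    sign = preference_sign(counts_l.o, counts_h.o, syn_l, syn_h)

    e_l, ehat_l, chi2_l = chi2_for_sample(counts_l, groups, index)
    e_h, ehat_h, chi2_h = chi2_for_sample(counts_h, groups, index)

    frame = pd.DataFrame(
        {
            "dipeptide": list(index.dipeptides),
            "bicodon": list(index.bicodons),
            "o_L": counts_l.o,
            "o_H": counts_h.o,
            "rsbu_L": rsbu_l,
            "rsbu_H": rsbu_h,
            "pi": pi,
            "p_value": p,
            "S": sign,
            "signed_logp": signed_logp(p, sign),
            "e_L": e_l,
            "e_H": e_h,
            "ehat_L": ehat_l,
            "ehat_H": ehat_h,
            "chi2_L": chi2_l,
            "chi2_H": chi2_h,
        }
    )
    if benjamini_hochberg:
        frame["p_bh"] = benjamini_hochberg_adjust(p)
    return frame


def benjamini_hochberg_adjust(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (emitted for convenience, never used to classify)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
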