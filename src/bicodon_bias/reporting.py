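"""Heat-map matrices, cross-organism tables, candidate filters, SNP reports.

The heat map arranges one value per bicodon (pause propensity pi or the
signed log p-value) on a 64 x 64 grid of P-site rows by A-site columns; the
192 cells whose P-site codon is a stop are masked (NaN), leaving the 3904
scored bicodons.  Rows and columns are ordered by average-linkage
hierarchical clustering of the codon profile vectors so codons with similar
pairing preferences sit together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .codes import CODONS, CODON_TO_INDEX, BicodonIndex, standard_code
from .sequence_io import CodingSequence

log = logging.getLogger(__name__)


@dataclass
class HeatmapMatrix:
    """A clustered 64 x 64 bicodon value grid (stop P-site rows masked)."""

    values: np.ndarray               # 64 x 64, NaN where masked
    row_order: np.ndarray            # permutation of 0..63 (P-site codons)
    col_order: np.ndarray            # permutation of 0..63 (A-site codons)

    @property
    def row_labels(self) -> list[str]:
        return [CODONS[i] for i in self.row_order]

    @property
    def col_labels(self) -> list[str]:
        return [CODONS[i] for i in self.col_order]

    def ordered(self) -> np.ndarray:
        return self.values[np.ix_(self.row_order, self.col_order)]


@dataclass
class SnpReport:
    """Pause-propensity consequences of one synonymous codon substitution."""

    gene_id: str
    codon_pos: int                   # 1-based
    ref_codon: str
    alt_codon: str
    upstream_ref: str | None         # bicodon (prev, ref), None at the 5' edge
    upstream_alt: str | None
    pi_upstream_ref: float | None
    pi_upstream_alt: float | None
    delta_pi_upstream: float | None
    downstream_ref: str | None       # bicodon (ref, next), None at the 3' edge
    downstream_alt: str | None
    pi_downstream_ref: float | None
    pi_downstream_alt: float | None
    delta_pi_downstream: float | None
    rscu_ref: float | None
    rscu_alt: float | None


def _leaf_order(link: np.ndarray, n: int) -> np.ndarray:
    """Deterministic dendrogram leaf order: at every internal node the child
    subtree containing the smallest leaf index comes first."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, _, _) in enumerate(link):
        left, right = members.pop(int(a)), members.pop(int(b))
        if min(right) < min(left):
            left, right = right, left
        members[n + k] = left + right
    (order,) = members.values()
    return np.array(order, dtype=np.int64)


def cluster_axes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage (UPGMA) ordering of both axes of a value grid.

    Rows and columns are clustered independently on Euclidean distances
    between their profile vectors; masked cells are treated as 0.  Leaf order
    is deterministic (smallest-leaf-first subtree orientation).
    """
    filled = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)

    def one_axis(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 3:
            return np.arange(mat.shape[0])
        # condense explicitly: a square all-zero profile matrix would otherwise
        # be mistaken for an uncondensed distance matrix by scipy
        link = linkage(pdist(mat, metric="euclidean"), method="average")
        return _leaf_order(link, mat.shape[0])

    return one_axis(filled), one_axis(filled.T)


def stats_to_grid(stats: pd.DataFrame, index: BicodonIndex, measure: str) -> np.ndarray:
    """Scatter a per-bicodon column onto the 64 x 64 (P, A) grid, NaN-masked."""
    grid = np.full((64, 64), np.nan)
    grid[index.p64, index.a64] = stats[measure].to_numpy(dtype=float)
    return grid


def export_heatmap(
    stats: pd.DataFrame,
    index: BicodonIndex,
    measure: str = "pi",
    orders: tuple[np.ndarray, np.ndarray] | None = None,
) -> HeatmapMatrix:
    """Build the clustered heat-map matrix for one per-bicodon measure.

    ``orders`` reuses a previous clustering (to keep cell positions
    comparable across organisms); by default the axes are clustered on this
    matrix's own values.
    """
    if measure not in stats.columns:
        raise KeyError(f"no column {measure!r} in stats table")
    grid = stats_to_grid(stats, index, measure)
    if orders is None:
        orders = cluster_axes(grid)
    return HeatmapMatrix(values=grid, row_order=orders[0], col_order=orders[1])


def write_heatmap_tsv(hm: HeatmapMatrix, path: str | Path) -> None:
    """Clustered matrix as TSV: first column P-site codon, header A-site codons."""
    ordered = hm.ordered()
    with open(path, "w") as fh:
        fh.write("#p_site\t" + "\t".join(hm.col_labels) + "\n")
        for label, row in zip(hm.row_labels, ordered):
            cells = "\t".join("" if np.isnan(v) else f"{v:.10g}" for v in row)
            fh.write(f"{label}\t{cells}\n")


def read_heatmap_tsv(path: str | Path) -> HeatmapMatrix:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        col_labels = header[1:]
        rows, row_labels = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            rows.append([np.nan if v == "" else float(v) for v in parts[1:]])
    row_order = np.array([CODON_TO_INDEX[c] for c in row_labels], dtype=np.int64)
    col_order = np.array([CODON_TO_INDEX[c] for c in col_labels], dtype=np.int64)
    values = np.full((64, 64), np.nan)
    values[np.ix_(row_order, col_order)] = np.array(rows, dtype=float)
    return HeatmapMatrix(values=values, row_order=row_order, col_order=col_order)


def render_heatmap(hm: HeatmapMatrix, path: str | Path, title: str = "") -> None:
    """Thin matplotlib veneer over the matrix (diverging map, masked cells grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = np.ma.masked_invalid(hm.ordered())
    fig, ax = plt.subplots(figsize=(10, 10))
    lim = float(np.nanmax(np.abs(hm.values))) or 1.0
    im = ax.imshow(ordered, cmap="RdBu_r", vmin=-lim, vmax=lim, interpolation="nearest")
    ax.set_xlabel("A-site codon (clustered)")
    ax.set_ylabel("P-site codon (clustered)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def filter_unexplained(
    stats: pd.DataFrame,
    direction: str,
    alpha: float = 0.01,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Bicodons passing p < alpha, max(z_L, z_H) >= z_threshold, pi-sign matched."""
    for col in ("p_value", "pi", "z_L", "z_H"):
        if col not in stats.columns:
            raise KeyError(f"stats table lacks column {col!r}")
    z = np.fmax(stats["z_L"].to_numpy(float), stats["z_H"].to_numpy(float))
    keep = (stats["p_value"].to_numpy(float) < alpha) & (z >= z_threshold)
    pi = stats["pi"].to_numpy(float)
    keep &= (pi > 0) if direction == "low" else (pi < 0)
    return stats.loc[keep]


def shared_bicodons(
    per_organism: Mapping[str, pd.DataFrame],
    alpha: float = 0.01,
    z_threshold: float = 3.0,
    direction: str = "low",
) -> pd.DataFrame:
    """Bicodons unexplained-and-biased in the same direction in every organism.

    Output mirrors the cross-organism summary tables: dipeptide, bicodon, one
    raw chi2_L + chi2_H column and one -log10 p column per organism (plus the
    z-unit combined deviation per organism, since the raw-vs-SD unit of the
    printed tables is ambiguous).
    """
    if not per_organism:
        raise ValueError("need at least one organism")
    names = list(per_organism)
    first = per_organism[names[0]]
    for name in names[1:]:
        if not (per_organism[name]["bicodon"].to_numpy() == first["bicodon"].to_numpy()).all():
            raise ValueError(f"bicodon index mismatch for organism {name!r}")
    kept = None
    for name in names:
        sel = set(filter_unexplained(per_organism[name], direction, alpha, z_threshold)["bicodon"])
        kept = sel if kept is None else kept & sel
    kept_mask = first["bicodon"].isin(sorted(kept))
    out = first.loc[kept_mask, ["dipeptide", "bicodon"]].reset_index(drop=True)
    for name in names:
        t = per_organism[name].set_index("bicodon").loc[out["bicodon"]]
        out[f"chi2_sum_{name}"] = (t["chi2_L"] + t["chi2_H"]).to_numpy()
        out[f"z_max_{name}"] = np.fmax(t["z_L"].to_numpy(float), t["z_H"].to_numpy(float))
        out[f"neg_log10_p_{name}"] = -np.log10(t["p_value"].to_numpy(float))
    return out


def occupancy_candidates(
    stats: pd.DataFrame,
    occupancy: Mapping[str, float],
    pi_min: float = 0.75,
    alpha: float = 0.01,
    occ_min: float = 0.03,
) -> pd.DataFrame:
    """Pause-candidate bicodons: pi > pi_min, p < alpha, occupancy > occ_min.

    All three inequalities are strict.  Bicodons absent from the occupancy
    table are excluded with a logged warning count.
    """
    missing = [b for b in stats["bicodon"] if b not in occupancy]
    if missing:
        log.warning("%d bicodons lack occupancy values; excluded", len(missing))
    occ = stats["bicodon"].map(occupancy)
    keep = (
        (stats["pi"] > pi_min)
        & (stats["p_value"] < alpha)
        & occ.notna()
        & (occ > occ_min)
    )
    out = stats.loc[keep].copy()
    out["occupancy"] = occ[keep]
    return out


def read_occupancy_tsv(path: str | Path) -> dict[str, float]:
    """Two-column TSV (bicodon, cumulative ribosome occupancy)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            bicodon, value = line.split("\t")[:2]
            out[bicodon] = float(value)
    return out


def snp_effect(
    cds: CodingSequence,
    codon_pos: int,
    alt_codon: str,
    stats: pd.DataFrame,
    codon_rscu: Mapping[str, float] | None = None,
) -> SnpReport:
    """Pause-propensity report for one synonymous codon substitution.

    Looks up pi for the reference and variant forms of both flanking bicodons
    (prev+codon and codon+next); values missing from the stats table are
    reported as None, not zero.  ``codon_rscu`` optionally supplies relative
    synonymous codon usage for the reference and variant codons.
    """
    table = standard_code()
    codons = cds.codons()
    if not (1 <= codon_pos <= len(codons)):
        raise ValueError(f"codon_pos {codon_pos} outside 1..{len(codons)}")
    ref = codons[codon_pos - 1]
    alt = alt_codon.upper().replace("U", "T")
    if table.amino_acid(ref) != table.amino_acid(alt):
        raise ValueError(
            f"{ref} -> {alt} is not synonymous "
            f"({table.amino_acid(ref)} vs {table.amino_acid(alt)})"
        )
    pi_of = dict(zip(stats["bicodon"], stats["pi"].astype(float)))

    def look(b: str | None) -> float | None:
        if b is None:
            return None
        v = pi_of.get(b)
        return None if v is None else float(v)

    prev = codons[codon_pos - 2] if codon_pos >= 2 else None
    nxt = codons[codon_pos] if codon_pos < len(codons) else None
    up_ref = prev + ref if prev else None
    up_alt = prev + alt if prev else None
    down_ref = ref + nxt if nxt else None
    down_alt = alt + nxt if nxt else None

    pur, pua = look(up_ref), look(up_alt)
    pdr, pda = look(down_ref), look(down_alt)
    return SnpReport(
        gene_id=cds.id,
        codon_pos=codon_pos,
        ref_codon=ref,
        alt_codon=alt,
        upstream_ref=up_ref,
        upstream_alt=up_alt,
        pi_upstream_ref=pur,
        pi_upstream_alt=pua,
        delta_pi_upstream=None if None in (pur, pua) else pua - pur,
        downstream_ref=down_ref,
        downstream_alt=down_alt,
        pi_downstream_ref=pdr,
        pi_downstream_alt=pda,
        delta_pi_downstream=None if None in (pdr, pda) else pda - pdr,
        rscu_ref=None if codon_rscu is None else codon_rscu.get(ref),
        rscu_alt=None if codon_rscu is None else codon_rscu.get(alt),
    )


def write_stats_tsv(stats: pd.DataFrame, path: str | Path) -> None:
    """Per-bicodon table as TSV with a single '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(stats.columns) + "\n")
        stats.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_stats_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        return pd.read_csv(fh, sep="\t", names=header)
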