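"""End-to-end pipeline: sample selection through classification and reports.

Each stage writes plain TSV so any intermediate can be inspected or re-fed to
the matching CLI subcommand; a JSON manifest records the configuration, the
seeds, and a checksum of every input and output so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codes import enumerate_bicodons
from .counting import build_groups, count_sample
from .reporting import (
    export_heatmap,
    occupancy_candidates,
    read_occupancy_tsv,
    write_heatmap_tsv,
    write_stats_tsv,
)
from .sampling import SamplerConfig, dedupe_isoforms, select_length_matched
from .sequence_io import (
    AbundanceRecord,
    CodingSequence,
    join_sequences_abundance,
    read_abundance_table,
    read_cds_fasta,
    write_abundance_table,
)
from .shuffle import classify_bicodons, null_moments, standardize_residuals
from .stats import compute_bicodon_stats

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    abundance: str
    out_dir: str
    occupancy: str | None = None
    n_select: int = 500
    sampler_sigma: float | None = None
    sampler_l_o: float | None = None
    sampler_seed: int = 0
    null_reps: int = 200
    null_seed: int = 0
    alpha: float = 0.01
    z_threshold: float = 3.0
    pi_min: float = 0.75
    occ_min: float = 0.03
    rsbu_normalization: str = "per_sample"
    factorial_mode: str = "lgamma"
    fisher_background: str = "group"
    combine_rule: str = "max"
    strip_versions: bool = False

    def __post_init__(self) -> None:
        if self.null_reps < 2:
            raise ValueError("null_reps must be >= 2")
        for name in ("alpha", "z_threshold", "pi_min", "occ_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run selection, counting, statistics, shuffle null, classification and
    reports; returns the output directory (with ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {"fasta": config.fasta, "abundance": config.abundance}
    if config.occupancy:
        inputs["occupancy"] = config.occupancy

    def stage(name: str):
        log.info("stage: %s", name)

    stage("load")
    seqs = read_cds_fasta(config.fasta)
    records = read_abundance_table(config.abundance)
    records = dedupe_isoforms(records)

    stage("sample")
    sampler = dict(n_select=config.n_select, l_o=config.sampler_l_o,
                   sigma=config.sampler_sigma, seed=config.sampler_seed)
    low = select_length_matched(records, SamplerConfig(direction="low", **sampler))
    high = select_length_matched(records, SamplerConfig(direction="high", **sampler))
    write_abundance_table(low, out / "sample_low.tsv")
    write_abundance_table(high, out / "sample_high.tsv")

    by_id = {s.id: s for s in seqs}
    seqs_low = _resolve(low, by_id, config.strip_versions, seqs)
    seqs_high = _resolve(high, by_id, config.strip_versions, seqs)

    stage("count")
    index = enumerate_bicodons()
    counts_l = count_sample(seqs_low, index)
    counts_h = count_sample(seqs_high, index)
    groups = build_groups(index, counts_l, counts_h)

    stage("stats")
    stats = compute_bicodon_stats(
        counts_l, counts_h, index, groups,
        rsbu_normalization=config.rsbu_normalization,  # type: ignore[arg-type]
        factorial_mode=config.factorial_mode,  # type: ignore[arg-type]
        fisher_background=config.fisher_background,  # type: ignore[arg-type]
    )

    stage("null")
    mom_l = null_moments(seqs_low, index, groups, config.null_reps, config.null_seed)
    mom_h = null_moments(seqs_high, index, groups, config.null_reps, config.null_seed + 1)
    stats["z_L"] = standardize_residuals(stats["chi2_L"].to_numpy(), mom_l)
    stats["z_H"] = standardize_residuals(stats["chi2_H"].to_numpy(), mom_h)

    stage("classify")
    stats["category"] = classify_bicodons(
        stats["p_value"].to_numpy(), stats["pi"].to_numpy(),
        stats["z_L"].to_numpy(), stats["z_H"].to_numpy(),
        alpha=config.alpha, z_threshold=config.z_threshold,
        combine=config.combine_rule,  # type: ignore[arg-type]
        moments_l=mom_l, moments_h=mom_h,
        chi2_l=stats["chi2_L"].to_numpy(), chi2_h=stats["chi2_H"].to_numpy(),
    ).to_numpy()
    write_stats_tsv(stats, out / "bicodon_stats.tsv")
    null_tbl = pd.DataFrame({
        "bicodon": stats["bicodon"], "mean_L": mom_l.mean, "sd_L": mom_l.sd,
        "mean_H": mom_h.mean, "sd_H": mom_h.sd,
        "z_L": stats["z_L"], "z_H": stats["z_H"], "category": stats["category"],
    })
    write_stats_tsv(null_tbl, out / "null_moments.tsv")

    stage("report")
    hm_pi = export_heatmap(stats, index, "pi")
    write_heatmap_tsv(hm_pi, out / "heatmap_pi.tsv")
    hm_p = export_heatmap(stats, index, "signed_logp",
                          orders=(hm_pi.row_order, hm_pi.col_order))
    write_heatmap_tsv(hm_p, out / "heatmap_signed_logp.tsv")
    if config.occupancy:
        occ = read_occupancy_tsv(config.occupancy)
        cand = occupancy_candidates(stats, occ, config.pi_min, config.alpha, config.occ_min)
        write_stats_tsv(cand, out / "occupancy_candidates.tsv")

    counts = stats["category"].value_counts()
    log.info("category counts: %s", counts.to_dict())

    manifest = {
        "tool": "bicodon-bias",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
        "category_counts": {str(k): int(v) for k, v in counts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _resolve(
    records: Sequence[AbundanceRecord],
    by_id: dict[str, CodingSequence],
    strip_versions: bool,
    all_seqs: Sequence[CodingSequence],
) -> list[CodingSequence]:
    """Sequences for the selected abundance records, abundances attached."""
    joined = join_sequences_abundance(
        [by_id[r.id] for r in records if r.id in by_id] or list(all_seqs),
        records,
        strip_versions=strip_versions,
    )
    if len(joined) != len(records):
        raise RuntimeError(
            f"only {len(joined)}/{len(records)} selected records have sequences"
        )
    return joined
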