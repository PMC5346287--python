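"""Reporting layer: clustered heat maps, cross-condition shared bicodons,
occupancy-filtered pause candidates, and a synonymous-SNP effect report.

Heat maps (pause propensity and signed log p, average-linkage clustered on
both codon axes) are written as TSV under results/.  The occupancy filter is
demonstrated with a synthetic per-bicodon occupancy table in which the
planted bicodons are given elevated occupancy, emulating how ribosome
profiling would corroborate genuine pause sites.  The SNP report picks a
synthetic gene and a synonymous variant inside a planted bicodon to show the
pause-propensity change such a substitution produces.
"""

import sys
from importlib import import_module
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
common = import_module("00_common")

from bicodon_bias import enumerate_bicodons
from bicodon_bias.reporting import (
    export_heatmap,
    occupancy_candidates,
    read_stats_tsv,
    shared_bicodons,
    snp_effect,
    write_heatmap_tsv,
    write_stats_tsv,
)
from bicodon_bias.sequence_io import read_cds_fasta


def synthetic_occupancy(index, stats, rng):
    """Synthetic cumulative ribosome occupancy: low background, elevated for
    the planted bicodons (stand-in for an external profiling-derived table)."""
    occ = dict(zip(index.bicodons, rng.uniform(0.0, 0.02, len(index))))
    for cp in common.PLANTED:
        occ[cp.p_site + cp.a_site] = 0.05
    return occ


def main() -> None:
    index = enumerate_bicodons()
    rng = np.random.default_rng(common.SEED)
    tables = {name: read_stats_tsv(common.stats_path(name)) for name in common.CONFIGS}

    for name, stats in tables.items():
        hm_pi = export_heatmap(stats, index, "pi")
        write_heatmap_tsv(hm_pi, common.RESULTS / f"{name}_heatmap_pi.tsv")
        hm_p = export_heatmap(
            stats, index, "signed_logp", orders=(hm_pi.row_order, hm_pi.col_order)
        )
        write_heatmap_tsv(hm_p, common.RESULTS / f"{name}_heatmap_signed_logp.tsv")
        print(f"{name}: heat maps written (|pi| max {np.nanmax(np.abs(hm_pi.values)):.2f})")

    shared = shared_bicodons({"planted": tables["planted"]}, direction="low")
    write_stats_tsv(shared, common.RESULTS / "low_preference_unexplained.tsv")
    print(f"planted condition: {len(shared)} low-preference unexplained bicodons")

    occ = synthetic_occupancy(index, tables["planted"], rng)
    cand = occupancy_candidates(tables["planted"], occ)
    write_stats_tsv(cand, common.RESULTS / "occupancy_candidates.tsv")
    print(f"pause candidates (pi > 0.75, p < 0.01, occupancy > 0.03): "
          f"{list(cand['bicodon'])}")

    # synonymous-variant report inside the strongest planted bicodon
    seqs = read_cds_fasta(common.sample_fasta("planted", "low"))
    target = common.PLANTED[0]
    bicodon = target.p_site + target.a_site
    for seq in seqs:
        codons = seq.codons()
        for pos in range(1, len(codons) - 1):
            if codons[pos - 1] + codons[pos] == bicodon:
                alt = "CGT"  # synonymous Arg variant of the planted A-site CGA
                rep = snp_effect(seq, pos + 1, alt, tables["planted"])
                print(
                    f"SNP report {seq.id} codon {pos + 1} {rep.ref_codon}->{alt}: "
                    f"upstream pi {rep.pi_upstream_ref:+.2f} -> {rep.pi_upstream_alt:+.2f} "
                    f"(delta {rep.delta_pi_upstream:+.2f})"
                )
                return


if __name__ == "__main__":
    main()
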