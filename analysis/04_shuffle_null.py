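"""Calibrate the residual scores against the 200-replicate codon-shuffle null
and classify every bicodon.

Shuffling codon order within each sequence (terminal stop fixed) preserves
codon usage but destroys pair correlations; chi2 recomputed on 200 shuffled
replicates per sample gives each bicodon's null mean and SD.  The observed
chi2 in SD units (z), together with the Fisher p-value and the sign of pi,
assigns one of four categories.  Appends z_L, z_H and category to the stats
tables and prints the category tally; on the null proteome essentially
everything should be `unbiased`, on the planted proteome the three planted
couplings should surface as `low_unexplained`.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
common = import_module("00_common")

from bicodon_bias import build_groups, count_sample, enumerate_bicodons
from bicodon_bias.reporting import read_stats_tsv, write_stats_tsv
from bicodon_bias.sequence_io import read_cds_fasta
from bicodon_bias.shuffle import classify_bicodons, null_moments, standardize_residuals


def main() -> None:
    index = enumerate_bicodons()
    for name in common.CONFIGS:
        seqs_l = read_cds_fasta(common.sample_fasta(name, "low"))
        seqs_h = read_cds_fasta(common.sample_fasta(name, "high"))
        cl = count_sample(seqs_l, index)
        ch = count_sample(seqs_h, index)
        groups = build_groups(index, cl, ch)
        stats = read_stats_tsv(common.stats_path(name))
        mom_l = null_moments(seqs_l, index, groups, common.NULL_REPS, common.SEED + 20)
        mom_h = null_moments(seqs_h, index, groups, common.NULL_REPS, common.SEED + 21)
        stats["z_L"] = standardize_residuals(stats["chi2_L"].to_numpy(), mom_l)
        stats["z_H"] = standardize_residuals(stats["chi2_H"].to_numpy(), mom_h)
        stats["category"] = classify_bicodons(
            stats["p_value"].to_numpy(), stats["pi"].to_numpy(),
            stats["z_L"].to_numpy(), stats["z_H"].to_numpy(),
        ).to_numpy()
        write_stats_tsv(stats, common.stats_path(name))
        tally = stats["category"].value_counts().to_dict()
        print(f"{name}: {tally}")
        if name == "planted":
            for cp in common.PLANTED:
                row = stats.iloc[index.lookup[cp.p_site + cp.a_site]]
                print(
                    f"  planted {cp.p_site}->{cp.a_site}: category={row['category']} "
                    f"pi={row['pi']:+.2f} p={row['p_value']:.2e} "
                    f"z_L={row['z_L']:.1f} z_H={row['z_H']:.1f}"
                )


if __name__ == "__main__":
    main()
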