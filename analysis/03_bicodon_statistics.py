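"""Count codons/bicodons in each sample and score every codon pair.

For each proteome this writes the full 3,904-row per-bicodon table
(results/<name>_bicodon_stats.tsv): observed counts in both samples, RSBU,
pause propensity pi, the two-sided Fisher p-value on the within-dipeptide
contingency table, the signed -S log10(p), and the codon-usage expectations
e, e_hat and residual chi2 per sample.  Prints the most extreme pause
propensities and the fraction of significantly biased bicodons.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
common = import_module("00_common")

from bicodon_bias import build_groups, count_sample, enumerate_bicodons
from bicodon_bias.reporting import write_stats_tsv
from bicodon_bias.sequence_io import read_cds_fasta
from bicodon_bias.stats import compute_bicodon_stats


def main() -> None:
    index = enumerate_bicodons()
    for name in common.CONFIGS:
        cl = count_sample(read_cds_fasta(common.sample_fasta(name, "low")), index)
        ch = count_sample(read_cds_fasta(common.sample_fasta(name, "high")), index)
        groups = build_groups(index, cl, ch)
        stats = compute_bicodon_stats(cl, ch, index, groups)
        write_stats_tsv(stats, common.stats_path(name))
        sig = (stats["p_value"] < 0.01).mean()
        top = stats.nlargest(3, "pi")[["bicodon", "pi", "p_value"]]
        print(f"{name}: N_p low={cl.n_p} high={ch.n_p} | {sig:.1%} of bicodons at p < 0.01")
        for _, row in top.iterrows():
            print(f"  highest pi: {row['bicodon']} pi={row['pi']:+.2f} p={row['p_value']:.2e}")


if __name__ == "__main__":
    main()
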