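"""Select the 500 lowest- and 500 highest-abundance coding sequences with
length-matched rejection sampling, for each proteome.

Writes the selected abundance tables and per-sample FASTA files under
results/data/ and prints the achieved length matching (gap in pooled SD
units) and the abundance contrast between the two samples.
"""

import sys
from importlib import import_module
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
common = import_module("00_common")

from bicodon_bias import SamplerConfig, dedupe_isoforms, select_length_matched
from bicodon_bias.sequence_io import (
    read_abundance_table,
    read_cds_fasta,
    write_abundance_table,
    write_cds_fasta,
)


def main() -> None:
    for name in common.CONFIGS:
        records = dedupe_isoforms(read_abundance_table(common.abundance_path(name)))
        seqs = {s.id: s for s in read_cds_fasta(common.fasta_path(name))}
        chosen = {}
        for i, direction in enumerate(("low", "high")):
            sel = select_length_matched(
                records,
                SamplerConfig(
                    n_select=common.N_SELECT,
                    direction=direction,
                    seed=common.SEED + 10 + i,
                ),
            )
            chosen[direction] = sel
            write_abundance_table(sel, common.sample_path(name, direction))
            write_cds_fasta([seqs[r.id] for r in sel], common.sample_fasta(name, direction))
        pooled_sd = np.std([r.cds_length for r in records])
        gap = abs(
            np.mean([r.cds_length for r in chosen["low"]])
            - np.mean([r.cds_length for r in chosen["high"]])
        )
        ab_lo = np.median([r.abundance for r in chosen["low"]])
        ab_hi = np.median([r.abundance for r in chosen["high"]])
        print(
            f"{name}: 500 + 500 selected | mean-length gap {gap:.0f} nt "
            f"({gap / pooled_sd:.2f} pooled SD) | median abundance "
            f"{ab_lo:.2f} vs {ab_hi:.0f} ppm ({ab_hi / ab_lo:.0f}x contrast)"
        )


if __name__ == "__main__":
    main()
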