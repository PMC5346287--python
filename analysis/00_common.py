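"""Shared paths and study conditions for the analysis scripts.

Two synthetic proteomes are analysed throughout:

* ``null`` — both expression classes use the same (uniform) codon profiles
  and there are no codon-pair couplings, so every downstream statistic is
  measured against a ground truth of "no bicodon preference at all".
* ``planted`` — the default class-dependent codon profiles plus three
  codon-pair couplings of strength 6 restricted to low-abundance genes
  (GTA->CGA, CGA->CCG, GCT->AGT), the kind of signal the pipeline exists to
  find.

Run the scripts in order from the repository root:

    python analysis/01_simulate_proteomes.py
    python analysis/02_select_samples.py
    ...
"""

from pathlib import Path

from bicodon_bias import Coupling, GeneratorConfig
from bicodon_bias.synthetic import uniform_profile

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

SEED = 20260930
N_GENES = 5000
N_SELECT = 500
NULL_REPS = 200

PLANTED = (
    Coupling("GTA", "CGA", 6.0, "low"),
    Coupling("CGA", "CCG", 6.0, "low"),
    Coupling("GCT", "AGT", 6.0, "low"),
)

CONFIGS = {
    "null": GeneratorConfig(
        n_genes=N_GENES,
        seed=SEED,
        codon_profile_low=uniform_profile(),
        codon_profile_high=uniform_profile(),
    ),
    "planted": GeneratorConfig(n_genes=N_GENES, seed=SEED + 1, couplings=PLANTED),
}


def fasta_path(name: str) -> Path:
    return DATA / f"{name}_cds.fa"


def abundance_path(name: str) -> Path:
    return DATA / f"{name}_abundance.tsv"


def sample_path(name: str, direction: str) -> Path:
    return DATA / f"{name}_sample_{direction}.tsv"


def sample_fasta(name: str, direction: str) -> Path:
    return DATA / f"{name}_sample_{direction}.fa"


def stats_path(name: str) -> Path:
    return RESULTS / f"{name}_bicodon_stats.tsv"
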