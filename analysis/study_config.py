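"""Shared configuration of the desk-scale synthetic feeding study.

Two serotypes, three conditions (wild type, ND169 feeding, DCR1 feeding),
three replicates each; 150 gene-overlapping endo-siRNA loci (10% phased) over
a stable background pool; 60k mapped reads per library with 40% feeding
reads in feeding conditions; 2-fold endo-siRNA depletion, doubled for
phased loci under DCR1 feeding; 98% target-mRNA knockdown. 300k reads per
library keeps per-locus counts high enough for the differential test while
the whole chain reruns in well under a minute.
"""

from pathlib import Path

from exofeed.simulate import SimulationConfig, default_library_design

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "study"
# alignments are tens of MB of regenerable SAM; keep them out of results/
ALIGN_DIR = Path(__file__).resolve().parent.parent / "scratch" / "study_alignments"


def get_config(seed: int = 42) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_scaffolds=2,
        scaffold_length=200_000,
        n_loci=150,
        phased_fraction=0.1,
        n_free_genes=30,
        n_background_loci=30,
        depth=200_000,
        locus_depletion_sigma=0.5,
        library_design=default_library_design(("51A", "51B"), 3),
    )
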