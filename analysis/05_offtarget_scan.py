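"""Exhaustive 23-mer off-target scan of both feeding fragments.

Enumerates every 23-mer window of each fragment plus reverse complements,
searches the rest of the genome for exact full-length occurrences, maps
unique matches to overlapping genes, and repeats the scan in the permissive
nt 2-16 seed-match mode.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import STUDY_DIR

from exofeed import io
from exofeed.intervals import parse_region
from exofeed.offtarget import (
    enumerate_kmers,
    map_hits_to_genes,
    scan_exact_matches,
    seed_match_scan,
)


def main() -> None:
    genome = io.read_fasta(STUDY_DIR / "genome.fa")
    genes = io.read_gff3(STUDY_DIR / "genes.gff3")
    fragments = json.loads((STUDY_DIR / "feeding_fragments.json").read_text())

    for cond, info in fragments.items():
        region = parse_region(info["region"])
        frag_seq = genome[region.scaffold][region.start : region.end]
        kmers = enumerate_kmers(frag_seq)
        hits = scan_exact_matches(kmers, genome, [region])
        hit_genes = map_hits_to_genes(hits, genes)
        seed_hits = seed_match_scan(kmers, genome, [region])
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(
            STUDY_DIR / f"offtarget_{cond}.tsv", sep="\t", index=False)
        print(f"{cond} fragment ({info['length']} bp, gene {info['gene_id']}): "
              f"{len(kmers)} query 23-mers, {len(hits)} exact hits outside the "
              f"fragment, {len(hit_genes)} off-target genes "
              f"({', '.join(hit_genes) or 'none'}); "
              f"{len(seed_hits)} nt2-16 seed matches")


if __name__ == "__main__":
    main()
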