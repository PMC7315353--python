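"""Normalize locus counts (KDCS vs TCS) and cluster the libraries.

Applies knockdown-corrected scaling per serotype, contrasts it with plain
total count scaling, tests the abundance shift of feeding vs wild-type
libraries (unpaired two-sided Wilcoxon on condition-merged normalized
counts), and writes complete-linkage dendrograms of the libraries.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import STUDY_DIR

from exofeed import io
from exofeed.normalize import normalize_by_batch
from exofeed.stats import (
    condition_means,
    forms_exclusive_clade,
    hierarchical_clustering,
    to_newick,
    wilcoxon_compare,
)


def main() -> None:
    matrix = io.read_counts_tsv(STUDY_DIR / "sirna_counts_quantified.tsv")
    meta = io.read_meta_tsv(STUDY_DIR / "library_meta_quantified.tsv")

    for method in ("kdcs", "tcs"):
        norm = normalize_by_batch(matrix, meta, method=method)
        io.write_tsv(norm, STUDY_DIR / f"sirna_{method}.tsv")

    kdcs_norm = io.read_counts_tsv(STUDY_DIR / "sirna_kdcs.tsv")
    for sero, grp in meta.groupby("serotype"):
        libs = list(grp.library_id)
        cm = condition_means(kdcs_norm[libs], grp)
        print(f"serotype {sero}: median KDCS-normalized locus count")
        for cond in cm.columns:
            p = (wilcoxon_compare(cm[cond], cm["WT"]) if cond != "WT" else np.nan)
            note = "" if cond == "WT" else f"  (Wilcoxon vs WT p={p:.2e})"
            print(f"  {cond:10s} {cm[cond].median():9.1f}{note}")
        z, labels = hierarchical_clustering(kdcs_norm[libs])
        (STUDY_DIR / f"dendrogram_{sero}.nwk").write_text(to_newick(z, labels) + "\n")
        wt = set(grp.loc[grp.condition == "WT", "library_id"])
        print(f"  WT replicates form an exclusive clade: "
              f"{forms_exclusive_clade(z, labels, wt)}")


if __name__ == "__main__":
    main()
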