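"""Differential expression of endo-siRNA loci and mRNAs per feeding
condition, with set intersections of the significant loci.

Raw counts, median-of-ratios size factors anchored on the stable background
loci (so a genome-wide depletion is not normalized away), per-feature
method-of-moments dispersion, NB Wald test, Benjamini-Hochberg at 0.05.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import STUDY_DIR

from exofeed import io
from exofeed.diffexpr import de_set_intersections, run_de
from exofeed.simulate import TARGET_GENES


def main() -> None:
    matrix = io.read_counts_tsv(STUDY_DIR / "sirna_counts_quantified.tsv")
    background = io.read_counts_tsv(STUDY_DIR / "background_counts.tsv")
    mrna = io.read_counts_tsv(STUDY_DIR / "mrna_counts.tsv")
    meta = io.read_meta_tsv(STUDY_DIR / "library_meta_quantified.tsv")
    non_target = mrna.index.difference(list(TARGET_GENES.values()))

    for sero, grp in meta.groupby("serotype"):
        libs = list(grp.library_id)
        combined = pd.concat([matrix, background])[libs]
        sets = {}
        for cond in ("ND169_KD", "DCR1_KD"):
            res = run_de(combined, grp, cond,
                         size_factor_features=background.index).loc[matrix.index]
            io.write_tsv(res, STUDY_DIR / f"de_sirna_{sero}_{cond}.tsv")
            sets[cond] = set(res.index[res.significant.fillna(False)])
            mres = run_de(mrna[libs], grp, cond, size_factor_features=non_target)
            io.write_tsv(mres, STUDY_DIR / f"de_mrna_{sero}_{cond}.tsv")
            print(f"{sero} {cond}: {len(sets[cond])}/{len(matrix)} endo-siRNA loci "
                  f"and {int(mres.significant.sum())}/{len(mrna)} mRNAs significant "
                  f"(target {TARGET_GENES[cond]} significant: "
                  f"{bool(mres.loc[TARGET_GENES[cond], 'significant'])})")
        inter = de_set_intersections(sets, set(matrix.index))
        print(f"{sero} intersections (UpSet-style): "
              + ", ".join(f"{'&'.join(k)}={v}" for k, v in sorted(inter.items())))


if __name__ == "__main__":
    main()
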