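"""Simulate the synthetic dsRNA-feeding study and write its inputs.

Generates the genome, gene annotation, endo-siRNA loci with phasing labels,
feeding fragments, per-library siRNA/mRNA counts and ground truth under
results/study/, plus one SAM file of error-free alignments per library.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import ALIGN_DIR, STUDY_DIR, get_config

from exofeed import io
from exofeed.pipeline import write_simulation
from exofeed.simulate import emit_library_alignments, simulate_dataset


def main() -> None:
    ds = simulate_dataset(get_config())
    write_simulation(ds, STUDY_DIR)
    samdir = ALIGN_DIR
    samdir.mkdir(parents=True, exist_ok=True)
    for lib in ds.library_meta.library_id:
        io.write_sam(emit_library_alignments(ds, lib), ds.genome, samdir / f"{lib}.sam")
    meta = ds.library_meta
    print(f"simulated {len(ds.loci)} endo-siRNA loci ({int(ds.loci.phased.sum())} phased), "
          f"{len(ds.background_loci)} background loci, {len(meta)} libraries")
    feeding = meta[meta.condition != "WT"]
    print(f"feeding read fraction: {(feeding.K / feeding['T']).mean():.3f} "
          f"(target {get_config().feeding_read_fraction})")
    print(f"outputs in {STUDY_DIR}")


if __name__ == "__main__":
    main()
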