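"""Deterministic readers and writers for the standard formats.

Writers produce byte-identical output for identical input (no timestamps,
fixed ordering, fixed float formatting), which the pipeline relies on for
reproducibility checks. Conventions: GFF3 is 1-based inclusive, BED is
0-based half-open with the phased flag in column 5 (0/1), SAM follows the
SAM spec via pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantify import ReadAlignment
from .simulate import SimulatedRead, reverse_complement


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.sort_values(["scaffold", "start"]).itertuples():
            fh.write(
                f"{g.scaffold}\texofeed\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                (attrs.get("ID", "?"), f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def write_bed(loci: pd.DataFrame, path, phased_column: str | None = "phased") -> None:
    """Loci as BED6; the phased flag (0/1) goes in the score column."""
    with open(path, "w") as fh:
        for row in loci.itertuples():
            score = (
                int(getattr(row, phased_column))
                if phased_column and hasattr(row, phased_column)
                else 0
            )
            strand = getattr(row, "strand", ".")
            fh.write(
                f"{row.scaffold}\t{row.start}\t{row.end}\t{row.locus_id}\t"
                f"{score}\t{strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(
                (
                    f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[5] if len(f) > 5 else ".",
                    bool(int(f[4])) if len(f) > 4 else False,
                )
            )
    return pd.DataFrame(
        rows, columns=["locus_id", "scaffold", "start", "end", "strand", "phased"]
    )


def write_sam(reads: list[SimulatedRead], genome: dict[str, str], path) -> None:
    """Error-free alignments as plain-text SAM against the given genome."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        tids = {name: i for i, name in enumerate(genome)}
        for r in reads:
            ref = genome[r.scaffold][r.start : r.end]
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.read_id
            # SAM stores SEQ on the forward reference strand; an error-free
            # alignment therefore always carries the reference bases.
            seg.query_sequence = ref
            seg.flag = 0 if r.strand == "+" else 16
            seg.reference_id = tids[r.scaffold]
            seg.reference_start = r.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{r.end - r.start}M"
            fh.write(seg)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"library_id", "condition", "T", "K"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"library metadata missing columns: {sorted(missing)}")
    return meta


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sam_to_read_alignments(path) -> list[ReadAlignment]:
    from .quantify import load_sam_alignments

    return load_sam_alignments(str(path))
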