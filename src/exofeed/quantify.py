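"""Small-RNA locus quantification.

Reads are filtered to the 21-25 nt siRNA size range and counted over
endo-siRNA loci and over the feeding-associated region. Counting follows
three rules:

* an alignment increments a locus if it overlaps it by at least 1 bp;
* a multi-mapping read contributes at most once per locus (multiple
  alignments of the same read inside one locus are deduplicated), so the
  same read may legitimately count towards several loci;
* the library total ``T`` is the number of distinct genome-mapped filtered
  reads, not the number of alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval


@dataclass(frozen=True)
class ReadAlignment:
    """One alignment of one read; coordinates 0-based half-open."""

    read_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LibraryMeta:
    """Per-library bookkeeping used by normalization.

    ``T`` is the total number of distinct genome-mapped 21-25 nt reads and
    ``K`` the number of feeding-associated reads (0 for wild type).
    """

    library_id: str
    serotype: str
    condition: str
    replicate: int
    T: int
    K: int

    def __post_init__(self) -> None:
        if not self.T >= self.K >= 0:
            raise ValueError(
                f"library {self.library_id}: require T >= K >= 0, got T={self.T}, K={self.K}"
            )


def filter_reads_by_length(
    alignments, min_len: int = 21, max_len: int = 25
) -> list[ReadAlignment]:
    """Keep alignments whose read length lies in [min_len, max_len], in order."""
    if min_len > max_len:
        raise ValueError(f"min_len={min_len} > max_len={max_len}")
    return [a for a in alignments if min_len <= a.length <= max_len]


def _locus_trees(loci: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in loci.itertuples():
        if not 0 <= row.start < row.end:
            raise ValueError(f"invalid locus interval {row.locus_id}")
        trees.setdefault(row.scaffold, IntervalTree()).addi(
            row.start, row.end, row.locus_id
        )
    return trees


def count_locus_reads(
    alignments,
    loci: pd.DataFrame,
    known_scaffolds: set[str] | None = None,
) -> tuple[pd.Series, int]:
    """Count distinct reads per locus for one library.

    Returns ``(counts indexed by locus_id, T)`` where T is the number of
    distinct genome-mapped reads. Raises if an alignment references a
    scaffold absent from ``known_scaffolds`` (when provided).
    """
    trees = _locus_trees(loci)
    seen_pairs: set[tuple[str, str]] = set()
    reads: set[str] = set()
    counts = dict.fromkeys(loci.locus_id, 0)
    for a in alignments:
        if known_scaffolds is not None and a.scaffold not in known_scaffolds:
            raise ValueError(f"alignment references unknown scaffold {a.scaffold!r}")
        reads.add(a.read_id)
        tree = trees.get(a.scaffold)
        if tree is None:
            continue
        for hit in tree.overlap(a.start, a.end):
            key = (a.read_id, hit.data)
            if key not in seen_pairs:
                seen_pairs.add(key)
                counts[hit.data] += 1
    return pd.Series(counts, name="count"), len(reads)


def count_feeding_reads(alignments, feeding_region: GenomicInterval) -> int:
    """Number of distinct reads overlapping the feeding region by >= 1 bp."""
    reads = {
        a.read_id
        for a in alignments
        if a.scaffold == feeding_region.scaffold
        and a.start < feeding_region.end
        and feeding_region.start < a.end
    }
    return len(reads)


def build_count_matrix(
    alignments_by_library: dict[str, list[ReadAlignment]],
    loci: pd.DataFrame,
    feeding_regions: dict[str, GenomicInterval] | None = None,
    known_scaffolds: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify several libraries into a locus x library raw count matrix.

    ``feeding_regions`` maps library_id -> feeding interval for feeding
    libraries (absent entries get K=0). Returns (matrix, totals) where
    totals has columns T and K indexed by library_id.
    """
    cols, totals = {}, []
    for lib_id, alns in alignments_by_library.items():
        counts, t = count_locus_reads(alns, loci, known_scaffolds)
        k = 0
        if feeding_regions and lib_id in feeding_regions:
            k = count_feeding_reads(alns, feeding_regions[lib_id])
        cols[lib_id] = counts
        totals.append((lib_id, t, k))
    matrix = pd.DataFrame(cols)
    totals_df = pd.DataFrame(totals, columns=["library_id", "T", "K"]).set_index(
        "library_id"
    )
    return matrix, totals_df


def strand_length_profile(
    alignments, locus: GenomicInterval
) -> tuple[int | None, int | None, dict[int, int]]:
    """Sense/antisense partition and 21-25 nt length histogram for one locus.

    Sense means the read strand agrees with the host gene's strand. For an
    unstranded locus the bias is undefined and (None, None) is returned;
    the histogram is reported either way and sums to the locus read count.
    """
    seen: set[str] = set()
    sense = antisense = 0
    hist = {n: 0 for n in range(21, 26)}
    for a in alignments:
        if not (
            a.scaffold == locus.scaffold and a.start < locus.end and locus.start < a.end
        ):
            continue
        if a.read_id in seen:
            continue
        seen.add(a.read_id)
        if a.length in hist:
            hist[a.length] += 1
        if locus.strand != ".":
            if a.strand == locus.strand:
                sense += 1
            else:
                antisense += 1
    if locus.strand == ".":
        return None, None, hist
    return sense, antisense, hist


def load_sam_alignments(path: str, drop_gapped: bool = True) -> list[ReadAlignment]:
    """Parse a SAM/BAM file into ReadAlignment records.

    Unmapped and secondary-duplicate records of the same read are kept (the
    counting rules deduplicate per locus); spliced or gapped alignments are
    rejected with a warning because siRNA reads align contiguously.
    """
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if drop_gapped and rec.cigartuples is not None:
                if any(op not in (0, 7, 8) for op, _ in rec.cigartuples):
                    warnings.warn(
                        f"dropping gapped/spliced alignment of read {rec.query_name}",
                        stacklevel=2,
                    )
                    continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    scaffold=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out
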