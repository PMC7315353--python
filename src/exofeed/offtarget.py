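"""Exhaustive k-mer off-target screening of dsRNA feeding fragments.

Every 23-mer window of the feeding fragment, together with its reverse
complement, is searched for exact, full-length, ungapped occurrences on the
forward strand of the genome outside the feeding region itself ("the rest
of the genome"). Because the query set contains both orientations,
strandedness of the genome scan is implicit. Genes overlapping a *unique*
exact match (a k-mer occurring exactly once outside the excluded region)
are the off-target candidates.

A seed-match mode restricts the query to nucleotide positions 2-16 of each
k-mer (1-based), the slicing-competent core reported for Argonaute-loaded
small RNAs, which is far more permissive than the full-length scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval
from .simulate import reverse_complement

_ACGT = set("ACGT")


@dataclass(frozen=True)
class KmerQuery:
    """A query k-mer with its source offsets in the fragment.

    ``offsets`` are 0-based window starts; reverse-complement k-mers carry
    the offset of the forward window they derive from.
    """

    sequence: str
    offsets: tuple[int, ...]
    orientation: str  # "forward" | "revcomp"


@dataclass(frozen=True)
class OffTargetHit:
    """One exact occurrence of a query k-mer outside the excluded region."""

    kmer: str
    fragment_offset: int
    orientation: str
    scaffold: str
    start: int
    end: int
    occurrences_in_rest: int
    unique: bool

    def __post_init__(self) -> None:
        if self.unique != (self.occurrences_in_rest == 1):
            raise ValueError("unique flag inconsistent with occurrence count")


def enumerate_kmers(fragment_sequence: str, k: int = 23) -> list[KmerQuery]:
    """All k-mer windows of a fragment plus their reverse complements.

    Windows containing non-ACGT symbols are skipped. Duplicated sequences
    are merged, keeping all source offsets; a sequence arising both forward
    and as a reverse complement is reported once, tagged forward.
    """
    seq = fragment_sequence.upper()
    if len(seq) < k:
        raise ValueError(
            f"fragment length {len(seq)} is shorter than k={k}"
        )
    found: dict[str, dict] = {}
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        if set(window) - _ACGT:
            continue
        for s, orient in ((window, "forward"), (reverse_complement(window), "revcomp")):
            entry = found.setdefault(s, {"offsets": [], "orientation": orient})
            entry["offsets"].append(off)
            if orient == "forward":
                entry["orientation"] = "forward"
    return [
        KmerQuery(s, tuple(sorted(set(e["offsets"]))), e["orientation"])
        for s, e in found.items()
    ]


def _excluded_overlaps(
    scaffold: str, start: int, end: int, excluded: list[GenomicInterval]
) -> bool:
    return any(
        iv.scaffold == scaffold and start < iv.end and iv.start < end
        for iv in excluded
    )


def scan_exact_matches(
    kmers: list[KmerQuery],
    genome: dict[str, str],
    excluded: list[GenomicInterval] | None = None,
) -> list[OffTargetHit]:
    """Exhaustive exact full-length search of query k-mers in a genome.

    Scans the forward strand of every scaffold; occurrences overlapping an
    excluded interval by any base are not counted. ``occurrences_in_rest``
    is the query's total occurrence count across the whole scan.
    """
    excluded = excluded or []
    queries: dict[str, KmerQuery] = {}
    lengths = set()
    for q in kmers:
        if set(q.sequence.upper()) - _ACGT:
            warnings.warn(
                f"skipping k-mer with non-ACGT symbols: {q.sequence!r}", stacklevel=2
            )
            continue
        queries[q.sequence.upper()] = q
        lengths.add(len(q.sequence))
    if not queries:
        return []

    raw: list[tuple[str, str, int, int]] = []  # kmer, scaffold, start, end
    per_kmer: dict[str, int] = {}
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        for k in sorted(lengths):
            for pos in range(len(seq) - k + 1):
                window = seq[pos : pos + k]
                if window in queries:
                    if _excluded_overlaps(scaffold, pos, pos + k, excluded):
                        continue
                    raw.append((window, scaffold, pos, pos + k))
                    per_kmer[window] = per_kmer.get(window, 0) + 1

    hits = []
    for kmer, scaffold, start, end in raw:
        q = queries[kmer]
        n = per_kmer[kmer]
        hits.append(
            OffTargetHit(
                kmer=kmer,
                fragment_offset=q.offsets[0],
                orientation=q.orientation,
                scaffold=scaffold,
                start=start,
                end=end,
                occurrences_in_rest=n,
                unique=(n == 1),
            )
        )
    hits.sort(key=lambda h: (h.scaffold, h.start, h.kmer))
    return hits


def map_hits_to_genes(
    hits: list[OffTargetHit], genes: pd.DataFrame, unique_only: bool = True
) -> list[str]:
    """Genes overlapping (>= 1 bp) the footprint of off-target hits.

    With ``unique_only`` (default) only hits whose k-mer matched exactly
    once outside the excluded region are considered; the alternative
    reading counts genes overlapping any exact match. Result is
    deduplicated and sorted by genomic position.
    """
    selected = [h for h in hits if h.unique or not unique_only]
    out: dict[str, tuple[str, int]] = {}
    for g in genes.itertuples():
        for h in selected:
            if h.scaffold == g.scaffold and h.start < g.end and g.start < h.end:
                out.setdefault(g.gene_id, (g.scaffold, g.start))
                break
    return sorted(out, key=lambda gid: out[gid])


def seed_match_scan(
    kmers: list[KmerQuery],
    genome: dict[str, str],
    excluded: list[GenomicInterval] | None = None,
    seed_start: int = 2,
    seed_end: int = 16,
) -> list[OffTargetHit]:
    """Scan only the seed portion (positions 2-16, 1-based) of each k-mer.

    Every full-length match is necessarily also a seed match, so this scan
    upper-bounds the full-length one.
    """
    if not kmers:
        return []
    k = len(kmers[0].sequence)
    if not 1 <= seed_start <= seed_end <= k:
        raise ValueError(
            f"seed interval [{seed_start}, {seed_end}] invalid for k={k}"
        )
    seeds: dict[str, KmerQuery] = {}
    for q in kmers:
        sub = q.sequence.upper()[seed_start - 1 : seed_end]
        if sub not in seeds:
            seeds[sub] = KmerQuery(sub, q.offsets, q.orientation)
    return scan_exact_matches(list(seeds.values()), genome, excluded)
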