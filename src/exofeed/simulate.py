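"""Synthetic dsRNA-feeding experiments with known ground truth.

The generator emulates the statistical structure of an RNAi-by-feeding study
in *Paramecium*: small-RNA libraries in which a large fraction of reads
derives from the fed dsRNA fragment, genome-wide depletion of endogenous
siRNA loci relative to a stable background read pool, stronger depletion of
phased loci when the Dicer gene itself is silenced, and near-complete
knockdown of the target mRNA.

Counts are negative-binomially distributed around condition-dependent means.
For a feeding library with total depth ``D`` and feeding-read fraction ``f``,
the feeding-associated read count is ``K ~ Binomial(D, f)`` and the remaining
``N = D - K`` reads are split between a stable background pool and the endo
siRNA loci: locus *i* draws ``NB((1-b)·w_i·phi_i·N, alpha)`` where ``b`` is
the background share, ``w_i`` the locus's relative abundance and ``phi_i``
its condition fold change. The background pool receives the complement
``N·(1 - (1-b)·sum_i(w_i·phi_i))`` so that the expected non-feeding pool is
condition-stable — sequencing capacity freed by depleted loci is soaked up
by the dominant stable pool. Under this design the knockdown-corrected
scaling estimator recovers ``phi`` without bias, while plain total count
scaling is biased by a factor ``(1-f)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

CONDITIONS = ("WT", "ND169_KD", "DCR1_KD")

#: feeding condition -> target gene label used in the synthetic annotation
TARGET_GENES = {"ND169_KD": "ND169", "DCR1_KD": "DCR1"}

# Fixed per-purpose offsets so that adding a library or a module does not
# perturb draws made by another stream.
_STREAM_GENOME = 11
_STREAM_WEIGHTS = 23
_STREAM_SIRNA = 37
_STREAM_MRNA = 53
_STREAM_READS = 71


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    serotype: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def is_feeding(self) -> bool:
        return self.condition != "WT"


def default_library_design(
    serotypes: tuple[str, ...] = ("51A", "51B"), n_replicates: int = 2
) -> tuple[LibrarySpec, ...]:
    """Two serotypes, wild type plus two feeding conditions, two replicates."""
    design = []
    for sero in serotypes:
        for cond in CONDITIONS:
            for rep in range(1, n_replicates + 1):
                design.append(LibrarySpec(f"{sero}_{cond}_r{rep}", sero, cond, rep))
    return tuple(design)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic feeding experiment.

    Proportions are in [0, 1]; ``depth`` is the expected number of
    genome-mapped 21-25 nt reads per library; fold changes are linear-scale
    multipliers (``locus_depletion=0.5`` halves endo-siRNA locus abundance
    in feeding conditions).
    """

    seed: int = 42
    n_scaffolds: int = 2
    scaffold_length: int = 500_000
    n_loci: int = 500
    phased_fraction: float = 0.1
    n_background_loci: int = 50
    library_design: tuple[LibrarySpec, ...] = field(
        default_factory=default_library_design
    )
    depth: int = 2_000_000
    feeding_read_fraction: float = 0.4
    background_share: float = 0.8
    locus_depletion: float = 0.5
    locus_depletion_sigma: float = 0.0
    phased_extra_depletion: float = 0.5
    nb_dispersion: float = 0.05
    mrna_knockdown_fc: float = 0.02
    mrna_global_fc: float = 0.9
    mrna_target_mean: float = 5_000.0
    mrna_base_mean: float = 500.0
    mrna_region_filtered: bool = True
    n_free_genes: int = 50
    gene_length: int = 1_500
    locus_length: int = 400
    fragment_length: int = 600
    intergenic_gap: int = 100
    feeding_pad: int = 100
    weight_sigma: float = 0.8

    def __post_init__(self) -> None:
        for name in ("phased_fraction", "feeding_read_fraction", "background_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.locus_depletion <= 0:
            raise ValueError("locus_depletion must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not self.library_design:
            raise ValueError("library_design must be non-empty")
        if self.fragment_length < 200:
            raise ValueError("feeding fragments must be at least 200 bp")
        if self.locus_length < 25:
            raise ValueError("loci must be at least 25 bp (longest read)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class FeedingFragment:
    """The genomic segment cloned into the dsRNA-production construct."""

    gene_id: str
    interval: GenomicInterval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError("fragment sequence length must equal interval length")


@dataclass
class SimulatedDataset:
    """Everything a synthetic study produces, plus the applied ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: pd.DataFrame  # gene_id, scaffold, start, end, strand, kind
    loci: pd.DataFrame  # locus_id, scaffold, start, end, strand, host_gene, phased
    background_loci: pd.DataFrame
    feeding_fragments: dict[str, FeedingFragment]  # keyed by condition
    sirna_counts: pd.DataFrame | None = None  # loci x libraries, raw
    background_counts: pd.DataFrame | None = None
    library_meta: pd.DataFrame | None = None  # library_id, serotype, condition, replicate, T, K
    mrna_counts: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def _place_features(config: SimulationConfig):
    """Lay out genes, loci and background loci sequentially, never overlapping.

    Raises a sizing error naming the constraint when the genome is too small.
    """
    gap = config.intergenic_gap
    n_genes = len(TARGET_GENES) + config.n_loci + config.n_free_genes
    needed = n_genes * (config.gene_length + gap) + config.n_background_loci * (
        config.locus_length + gap
    )
    available = config.n_scaffolds * config.scaffold_length
    if needed > available:
        raise ValueError(
            f"requested features need {needed} bp but the genome provides only "
            f"{available} bp ({config.n_scaffolds} x {config.scaffold_length}); "
            "increase scaffold_length/n_scaffolds or reduce n_loci/n_free_genes"
        )

    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    cursor = {s: 0 for s in scaffolds}
    sidx = 0

    def alloc(length: int) -> tuple[str, int, int]:
        nonlocal sidx
        for _ in range(len(scaffolds)):
            s = scaffolds[sidx % len(scaffolds)]
            if cursor[s] + length + gap <= config.scaffold_length:
                start = cursor[s] + gap
                cursor[s] = start + length
                sidx += 1
                return s, start, start + length
            sidx += 1
        raise ValueError(
            "ran out of genome space while placing features; "
            "increase scaffold_length or n_scaffolds"
        )

    genes, loci, background = [], [], []
    # knockdown target genes first, so their coordinates are stable
    for cond, gene_id in TARGET_GENES.items():
        s, a, b = alloc(config.gene_length)
        genes.append((gene_id, s, a, b, "+", "target"))
    for i in range(config.n_loci):
        gene_id = f"gene_{i + 1:05d}"
        strand = "+" if i % 2 == 0 else "-"
        s, a, b = alloc(config.gene_length)
        genes.append((gene_id, s, a, b, strand, "host"))
        off = (config.gene_length - config.locus_length) // 2
        loci.append(
            (f"locus_{i + 1:05d}", s, a + off, a + off + config.locus_length, strand, gene_id)
        )
    for i in range(config.n_free_genes):
        s, a, b = alloc(config.gene_length)
        genes.append((f"freegene_{i + 1:04d}", s, a, b, "+" if i % 2 else "-", "free"))
    for i in range(config.n_background_loci):
        s, a, b = alloc(config.locus_length)
        background.append((f"background_{i + 1:04d}", s, a, b, "."))

    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "scaffold", "start", "end", "strand", "kind"]
    )
    loci_df = pd.DataFrame(
        loci, columns=["locus_id", "scaffold", "start", "end", "strand", "host_gene"]
    )
    background_df = pd.DataFrame(
        background, columns=["locus_id", "scaffold", "start", "end", "strand"]
    )
    return genes_df, loci_df, background_df


def generate_genome_and_annotation(config: SimulationConfig) -> SimulatedDataset:
    """Generate scaffolds, gene models, endo-siRNA loci and feeding fragments.

    Base composition is uniform over ACGT. Genes never overlap, every locus
    lies inside its host gene, and ``round(phased_fraction * n_loci)`` loci
    are flagged phased. One feeding fragment per knockdown gene is copied
    verbatim from the genome.
    """
    rng = config.rng(_STREAM_GENOME)
    genome = {
        f"scaffold_{i + 1}": "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=config.scaffold_length)]
        )
        for i in range(config.n_scaffolds)
    }
    genes, loci, background = _place_features(config)

    n_phased = round(config.phased_fraction * config.n_loci)
    phased_idx = rng.choice(config.n_loci, size=n_phased, replace=False)
    phased = np.zeros(config.n_loci, dtype=bool)
    phased[phased_idx] = True
    loci = loci.assign(phased=phased)

    fragments = {}
    for cond, gene_id in TARGET_GENES.items():
        g = genes.loc[genes.gene_id == gene_id].iloc[0]
        off = (config.gene_length - config.fragment_length) // 2
        iv = GenomicInterval(g.scaffold, g.start + off, g.start + off + config.fragment_length, "+")
        fragments[cond] = FeedingFragment(
            gene_id, iv, genome[iv.scaffold][iv.start : iv.end]
        )

    return SimulatedDataset(
        config=config,
        genome=genome,
        genes=genes,
        loci=loci,
        background_loci=background,
        feeding_fragments=fragments,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mean + alpha*mean^2; Poisson in the alpha=0 limit."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("negative NB mean")
    if alpha == 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


_STREAM_DEPLETION = 29


def locus_fold_changes(config: SimulationConfig, loci: pd.DataFrame) -> pd.DataFrame:
    """True per-locus fold change applied in each condition (linear scale).

    With ``locus_depletion_sigma > 0`` each locus gets its own response,
    lognormal around ``locus_depletion`` and shared between the two feeding
    conditions — emulating heterogeneous locus sensitivity, where only the
    strongly responding tail reaches locus-level significance.
    """
    fc = pd.DataFrame(1.0, index=loci.locus_id, columns=list(CONDITIONS))
    depletion = np.full(len(loci), config.locus_depletion)
    if config.locus_depletion_sigma > 0:
        rng = config.rng(_STREAM_DEPLETION)
        depletion = depletion * np.exp(
            rng.normal(0.0, config.locus_depletion_sigma, size=len(loci))
        )
    for cond in ("ND169_KD", "DCR1_KD"):
        fc[cond] = depletion
    phased = loci.set_index("locus_id").phased
    fc.loc[phased, "DCR1_KD"] *= config.phased_extra_depletion
    return fc


def simulate_sirna_counts(
    config: SimulationConfig,
    loci: pd.DataFrame,
    background_loci: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw per-library feeding, background and endo-siRNA locus read counts.

    Returns ``(sirna_counts, background_counts, library_meta, truth)``. The
    library total T is the sum of all simulated read categories and K is the
    feeding-associated count (0 for wild type).
    """
    wrng = config.rng(_STREAM_WEIGHTS)
    n_loci = len(loci)
    n_bg = len(background_loci)
    w = np.exp(wrng.normal(0.0, config.weight_sigma, size=n_loci))
    w /= w.sum()
    v = np.exp(wrng.normal(0.0, config.weight_sigma, size=n_bg))
    v /= v.sum()

    fc = locus_fold_changes(config, loci)
    rng = config.rng(_STREAM_SIRNA)
    b = config.background_share
    counts, bg_counts, meta = {}, {}, []
    for lib in config.library_design:
        if lib.is_feeding:
            k = int(rng.binomial(config.depth, config.feeding_read_fraction))
        else:
            k = 0
        n_rest = config.depth - k
        phi = fc[lib.condition].to_numpy()
        locus_mean = (1.0 - b) * w * phi * n_rest
        bg_total = n_rest * (1.0 - (1.0 - b) * float(np.sum(w * phi)))
        bg_mean = bg_total * v
        locus_c = _nb_draw(rng, locus_mean, config.nb_dispersion)
        # the background stands in for the aggregate of everything else that
        # maps; an aggregate of many independent sources has negligible
        # overdispersion, so it carries sequencing (Poisson) noise only --
        # this is what keeps the corrected library size T-K condition-stable
        bg_c = rng.poisson(bg_mean)
        t = int(k + locus_c.sum() + bg_c.sum())
        counts[lib.library_id] = locus_c
        bg_counts[lib.library_id] = bg_c
        meta.append((lib.library_id, lib.serotype, lib.condition, lib.replicate, t, k))

    sirna = pd.DataFrame(counts, index=loci.locus_id)
    bg = pd.DataFrame(bg_counts, index=background_loci.locus_id)
    meta_df = pd.DataFrame(
        meta, columns=["library_id", "serotype", "condition", "replicate", "T", "K"]
    )
    truth = {
        "locus_fold_change": fc,
        "locus_weights": pd.Series(w, index=loci.locus_id),
        "background_weights": pd.Series(v, index=background_loci.locus_id),
    }
    return sirna, bg, meta_df, truth


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulatedRead:
    """A single error-free 21-25 nt alignment, half-open coordinates."""

    read_id: str
    scaffold: str
    start: int
    end: int
    strand: str


def emit_sirna_alignments(
    counts: pd.Series,
    features: pd.DataFrame,
    genome: dict[str, str],
    seed: int,
    prefix: str = "read",
) -> list[SimulatedRead]:
    """Materialize each counted read as an error-free alignment.

    ``counts`` maps feature id -> read count for one library; ``features``
    provides the intervals (columns locus_id/scaffold/start/end). Each read
    has a length drawn uniformly from {21..25}, lies fully inside its
    feature, and a uniformly random strand. Deterministic given ``seed``.
    """
    rng = np.random.default_rng([int(seed), _STREAM_READS])
    feats = features.set_index("locus_id")
    reads: list[SimulatedRead] = []
    for feature_id, n in counts.items():
        n = int(n)
        if n == 0:
            continue
        row = feats.loc[feature_id]
        flen = int(row.end) - int(row.start)
        if flen < 25:
            raise ValueError(
                f"feature {feature_id} is {flen} bp, shorter than the longest read (25)"
            )
        if row.scaffold not in genome:
            raise ValueError(f"unknown scaffold {row.scaffold!r}")
        lengths = rng.integers(21, 26, size=n)
        offsets = rng.integers(0, flen - lengths + 1)
        strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
        for i in range(n):
            start = int(row.start) + int(offsets[i])
            reads.append(
                SimulatedRead(
                    read_id=f"{prefix}:{feature_id}:{i}",
                    scaffold=str(row.scaffold),
                    start=start,
                    end=start + int(lengths[i]),
                    strand=str(strands[i]),
                )
            )
    return reads


def emit_library_alignments(
    dataset: SimulatedDataset, library_id: str
) -> list[SimulatedRead]:
    """All reads of one library: endo-locus, background, and feeding reads."""
    if dataset.sirna_counts is None:
        raise ValueError("simulate counts before emitting alignments")
    lib = next(l for l in dataset.config.library_design if l.library_id == library_id)
    seed_base = dataset.config.seed * 1009 + hash_stable(library_id)
    reads = emit_sirna_alignments(
        dataset.sirna_counts[library_id],
        dataset.loci,
        dataset.genome,
        seed=seed_base,
        prefix=f"{library_id}:locus",
    )
    reads += emit_sirna_alignments(
        dataset.background_counts[library_id],
        dataset.background_loci,
        dataset.genome,
        seed=seed_base + 1,
        prefix=f"{library_id}:bg",
    )
    k = int(dataset.library_meta.set_index("library_id").loc[library_id, "K"])
    if k > 0:
        frag = dataset.feeding_fragments[lib.condition]
        frag_df = pd.DataFrame(
            [
                {
                    "locus_id": "feeding",
                    "scaffold": frag.interval.scaffold,
                    "start": frag.interval.start,
                    "end": frag.interval.end,
                }
            ]
        )
        reads += emit_sirna_alignments(
            pd.Series({"feeding": k}),
            frag_df,
            dataset.genome,
            seed=seed_base + 2,
            prefix=f"{library_id}:feed",
        )
    return reads


def hash_stable(s: str) -> int:
    """Deterministic small hash (Python's hash() is salted per process)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def target_effective_fraction(config: SimulationConfig) -> float:
    """Fraction of a target gene outside the padded feeding region.

    Fragments are centered in their gene; reads from the feeding region
    (padded by ``feeding_pad`` on each side) are discarded before mRNA
    quantification in feeding libraries, so the target gene's observable
    counts come from this fraction of its length only.
    """
    off = (config.gene_length - config.fragment_length) // 2
    a = max(0, off - config.feeding_pad)
    b = min(config.gene_length, off + config.fragment_length + config.feeding_pad)
    return max(1, config.gene_length - (b - a)) / config.gene_length


def simulate_mrna_counts(
    config: SimulationConfig, genes: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """NB mRNA counts per gene and library, with target-gene knockdown.

    In a feeding condition every gene's mean is multiplied by
    ``mrna_global_fc``; the condition's own target gene is additionally
    multiplied by ``mrna_knockdown_fc`` (e.g. 0.02 for a 98% knockdown) and
    thinned to the fraction of its length outside the padded feeding region,
    emulating removal of feeding-associated reads before quantification.
    """
    for gene_id in TARGET_GENES.values():
        if gene_id not in set(genes.gene_id):
            raise ValueError(f"knockdown gene {gene_id!r} missing from annotation")
    rng = config.rng(_STREAM_MRNA)
    n = len(genes)
    base = config.mrna_base_mean * np.exp(rng.normal(0.0, 1.0, size=n) - 0.5)
    base = pd.Series(base, index=genes.gene_id)
    for gene_id in TARGET_GENES.values():
        base[gene_id] = config.mrna_target_mean

    fc = pd.DataFrame(1.0, index=genes.gene_id, columns=list(CONDITIONS))
    for cond in ("ND169_KD", "DCR1_KD"):
        fc[cond] = config.mrna_global_fc
        fc.loc[TARGET_GENES[cond], cond] *= config.mrna_knockdown_fc

    # sampling depth lost to the feeding-region read filter of the target
    # gene (not part of the biological fold change recorded in truth);
    # disabled when counts are modelled as unfiltered
    thinning = pd.DataFrame(1.0, index=genes.gene_id, columns=list(CONDITIONS))
    if config.mrna_region_filtered:
        frac = target_effective_fraction(config)
        for cond in ("ND169_KD", "DCR1_KD"):
            thinning.loc[TARGET_GENES[cond], cond] = frac

    counts = {}
    for lib in config.library_design:
        mean = (
            base.to_numpy()
            * fc[lib.condition].to_numpy()
            * thinning[lib.condition].to_numpy()
        )
        counts[lib.library_id] = _nb_draw(rng, mean, config.nb_dispersion)
    mrna = pd.DataFrame(counts, index=genes.gene_id)
    truth = {"mrna_fold_change": fc, "mrna_base_mean": base}
    return mrna, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome, annotation, siRNA and mRNA counts."""
    ds = generate_genome_and_annotation(config)
    ds.sirna_counts, ds.background_counts, ds.library_meta, sirna_truth = (
        simulate_sirna_counts(config, ds.loci, ds.background_loci)
    )
    ds.mrna_counts, mrna_truth = simulate_mrna_counts(config, ds.genes)
    ds.truth = {**sirna_truth, **mrna_truth}
    return ds
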