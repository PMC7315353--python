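"""End-to-end orchestration of the synthetic feeding study.

``run_pipeline`` drives simulate -> quantify -> normalize -> differential
expression -> off-target scan -> expression statistics, writing every stage
product to the output directory plus a machine-readable ``report.json``.
Reruns with the same configuration and seed reproduce byte-identical
outputs.

The stage functions all live in their own modules and operate on standard
files (SAM, BED, GFF3, TSV), so the same analysis can be assembled piecewise
through the CLI subcommands for externally produced data.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, io, normalize, offtarget, quantify, stats
from .simulate import (
    TARGET_GENES,
    SimulatedDataset,
    SimulationConfig,
    emit_library_alignments,
    simulate_dataset,
)

log = logging.getLogger("exofeed")

REPORT_SECTIONS = (
    "feeding_reads",
    "knockdown_efficiency",
    "abundance_comparison",
    "differential_expression",
    "phasing",
    "offtarget",
    "clustering",
)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic-study run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "exofeed_out"
    normalization_method: str = "kdcs"
    significance_threshold: float = 0.05
    offtarget_k: int = 23
    offtarget_seed_mode: bool = False
    feeding_pad: int = 100
    pseudocount: float = 1.0
    quantify_from_alignments: bool = True
    de_mode: str = "grouped"  # or "per_library"

    def __post_init__(self) -> None:
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance threshold must lie in (0, 1)")
        if self.de_mode not in ("grouped", "per_library"):
            raise ValueError(f"unknown de_mode {self.de_mode!r}")


def validate_inputs(
    genome_path=None, gff_path=None, bed_path=None, meta_path=None
) -> list[str]:
    """Validate on-disk inputs; returns a list of violation messages."""
    errors: list[str] = []
    genome = None
    if genome_path is not None:
        try:
            genome = io.read_fasta(genome_path)
            if not genome:
                errors.append(f"{genome_path}: no FASTA records")
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            errors.append(f"{genome_path}: cannot parse FASTA ({exc})")
    if gff_path is not None:
        try:
            genes = io.read_gff3(gff_path)
            if genes.empty:
                errors.append(f"{gff_path}: no gene records")
            elif genome is not None:
                for g in genes.itertuples():
                    if g.scaffold not in genome:
                        errors.append(
                            f"{gff_path}: gene {g.gene_id} on unknown scaffold {g.scaffold}"
                        )
                    elif g.end > len(genome[g.scaffold]):
                        errors.append(
                            f"{gff_path}: gene {g.gene_id} extends past scaffold end"
                        )
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{gff_path}: cannot parse GFF3 ({exc})")
    if bed_path is not None:
        try:
            loci = io.read_bed(bed_path)
            for i, row in enumerate(loci.itertuples(), start=1):
                if not 0 <= row.start < row.end:
                    errors.append(f"{bed_path}:{i}: invalid interval")
                elif genome is not None and (
                    row.scaffold not in genome
                    or row.end > len(genome[row.scaffold])
                ):
                    errors.append(
                        f"{bed_path}:{i}: locus {row.locus_id} outside genome"
                    )
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{bed_path}: cannot parse BED ({exc})")
    if meta_path is not None:
        try:
            meta = io.read_meta_tsv(meta_path)
            for i, row in enumerate(meta.itertuples(), start=1):
                if not row.T >= row.K >= 0:
                    errors.append(
                        f"{meta_path}:{i}: library {row.library_id} violates T >= K >= 0"
                    )
                if row.T <= 0:
                    errors.append(
                        f"{meta_path}:{i}: library {row.library_id} has T <= 0"
                    )
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{meta_path}: cannot parse metadata ({exc})")
    return errors


def _stage(name: str):
    log.info("stage %s", name)
    return time.monotonic()


def _fragment_transcript_span(ds: SimulatedDataset, cond: str) -> tuple[str, int, int]:
    frag = ds.feeding_fragments[cond]
    gene = ds.genes.set_index("gene_id").loc[frag.gene_id]
    return frag.gene_id, frag.interval.start - gene.start, frag.interval.end - gene.start


def write_simulation(ds: SimulatedDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(ds.genome, outdir / "genome.fa")
    io.write_gff3(ds.genes, outdir / "genes.gff3")
    io.write_bed(ds.loci, outdir / "loci.bed")
    io.write_bed(ds.background_loci, outdir / "background_loci.bed", phased_column=None)
    io.write_tsv(ds.library_meta, outdir / "library_meta.tsv", index=False)
    io.write_tsv(ds.sirna_counts, outdir / "sirna_counts_true.tsv")
    io.write_tsv(ds.mrna_counts, outdir / "mrna_counts.tsv")
    truth = {
        "locus_fold_change": ds.truth["locus_fold_change"].round(6).to_dict(),
        "mrna_fold_change": ds.truth["mrna_fold_change"].round(6).to_dict(),
    }
    io.write_json(truth, outdir / "truth.json")
    frags = {
        cond: {
            "gene_id": f.gene_id,
            "region": f.interval.to_region_string(),
            "length": len(f.sequence),
        }
        for cond, f in ds.feeding_fragments.items()
    }
    io.write_json(frags, outdir / "feeding_fragments.json")


def quantify_stage(
    ds: SimulatedDataset, outdir: Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit per-library SAM alignments and re-quantify them from scratch.

    Counts both the endo-siRNA loci and the stable background loci; returns
    (endo matrix, background matrix, totals with T and K).
    """
    samdir = outdir / "alignments"
    samdir.mkdir(parents=True, exist_ok=True)
    lib_ids = list(ds.sirna_counts.columns)
    alignments = {}
    feeding_regions = {}
    cond_by_lib = {l.library_id: l.condition for l in ds.config.library_design}
    for lib_id in lib_ids:
        reads = emit_library_alignments(ds, lib_id)
        sam_path = samdir / f"{lib_id}.sam"
        io.write_sam(reads, ds.genome, sam_path)
        alns = quantify.filter_reads_by_length(io.sam_to_read_alignments(sam_path))
        alignments[lib_id] = alns
        cond = cond_by_lib[lib_id]
        if cond in ds.feeding_fragments:
            feeding_regions[lib_id] = ds.feeding_fragments[cond].interval
    all_loci = pd.concat(
        [ds.loci[["locus_id", "scaffold", "start", "end"]],
         ds.background_loci[["locus_id", "scaffold", "start", "end"]]],
        ignore_index=True,
    )
    combined, totals = quantify.build_count_matrix(
        alignments, all_loci, feeding_regions, set(ds.genome)
    )
    matrix = combined.loc[ds.loci.locus_id]
    bg_matrix = combined.loc[ds.background_loci.locus_id]
    io.write_tsv(matrix, outdir / "sirna_counts.tsv")
    io.write_tsv(bg_matrix, outdir / "background_counts.tsv")
    return matrix, bg_matrix, totals


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns the report dict (also written to
    ``<outdir>/report.json``)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    outdir = Path(config.outdir)
    report: dict = {"config": _config_dict(config)}
    t0 = _stage("simulate")
    ds = simulate_dataset(config.simulation)
    write_simulation(ds, outdir)
    meta = ds.library_meta
    log.info("simulate done in %.1fs", time.monotonic() - t0)

    t0 = _stage("quantify")
    if config.quantify_from_alignments:
        matrix, bg_matrix, totals = quantify_stage(ds, outdir)
        # quantified totals replace the simulated bookkeeping
        meta = meta.drop(columns=["T", "K"]).merge(
            totals.reset_index(), on="library_id"
        )
    else:
        matrix = ds.sirna_counts
        bg_matrix = ds.background_counts
        io.write_tsv(matrix, outdir / "sirna_counts.tsv")
    io.write_tsv(meta, outdir / "library_meta_quantified.tsv", index=False)
    log.info("quantify done in %.1fs", time.monotonic() - t0)

    t0 = _stage("normalize")
    normalized = normalize.normalize_by_batch(
        matrix, meta, method=config.normalization_method
    )
    io.write_tsv(normalized, outdir / f"sirna_{config.normalization_method}.tsv")
    meta_ix = meta.set_index("library_id")
    # feeding-region abundance (coverage-figure analogue) uses TCS only
    feeding_tcs = {}
    for lib in config.simulation.library_design:
        if not lib.is_feeding:
            continue
        t = float(meta_ix.loc[lib.library_id, "T"])
        k = float(meta_ix.loc[lib.library_id, "K"])
        sero_t = meta_ix.loc[meta_ix.serotype == lib.serotype, "T"].astype(float)
        feeding_tcs[lib.library_id] = {
            "condition": lib.condition,
            "serotype": lib.serotype,
            "K": k,
            "K_tcs_normalized": k * sero_t.max() / t,
            "feeding_read_fraction": k / t,
        }
    report["feeding_reads"] = feeding_tcs
    log.info("normalize done in %.1fs", time.monotonic() - t0)

    t0 = _stage("differential_expression")
    de_section: dict = {}
    sig_sets: dict[str, dict[str, set]] = {}
    serotypes = sorted(meta.serotype.unique())
    for sero in serotypes:
        sero_meta = meta[meta.serotype == sero]
        sero_libs = list(sero_meta.library_id)
        # size factors anchored on the stable background loci: plain
        # median-of-ratios over the endo loci alone would absorb a
        # genome-wide depletion (same rationale as KDCS)
        sero_counts = pd.concat([matrix, bg_matrix])[sero_libs]
        anchor = bg_matrix.index
        sero_sets: dict[str, set] = {}
        for cond in ("ND169_KD", "DCR1_KD"):
            if cond not in set(sero_meta.condition):
                continue
            if config.de_mode == "grouped":
                res = diffexpr.run_de(
                    sero_counts,
                    sero_meta,
                    cond,
                    alpha_threshold=config.significance_threshold,
                    size_factor_features=anchor,
                ).loc[matrix.index]
            else:
                frames = []
                wt_libs = sero_meta.loc[
                    sero_meta.condition == "WT", "library_id"
                ].tolist()
                for lib_id in sero_meta.loc[
                    sero_meta.condition == cond, "library_id"
                ]:
                    sub = sero_counts[wt_libs + [lib_id]]
                    frames.append(
                        diffexpr.run_de(
                            sub,
                            sero_meta,
                            cond,
                            alpha_threshold=config.significance_threshold,
                            size_factor_features=anchor,
                        )
                        .loc[matrix.index]
                        .assign(library=lib_id)
                    )
                res = pd.concat(frames)
            io.write_tsv(res, outdir / f"de_sirna_{sero}_{cond}.tsv")
            sero_sets[cond] = set(res.index[res.significant.fillna(False)])
            de_section[f"{sero}:{cond}"] = {
                "n_significant": int(res.significant.sum()),
                "n_tested": int(res.pvalue.notna().sum()),
            }
        if len(sero_sets) >= 2:
            inter = diffexpr.de_set_intersections(
                sero_sets, set(matrix.index)
            )
            de_section[f"{sero}:intersections"] = {
                "&".join(k): v for k, v in inter.items()
            }
        sig_sets[sero] = sero_sets

        # mRNA DE; target genes are excluded from size-factor estimation
        # (their counts carry the knockdown plus the feeding-region filter)
        mrna_sets: dict[str, set] = {}
        non_target = ds.mrna_counts.index.difference(list(TARGET_GENES.values()))
        for cond in ("ND169_KD", "DCR1_KD"):
            if cond not in set(sero_meta.condition):
                continue
            res = diffexpr.run_de(
                ds.mrna_counts[sero_libs],
                sero_meta,
                cond,
                alpha_threshold=config.significance_threshold,
                size_factor_features=non_target,
            )
            io.write_tsv(res, outdir / f"de_mrna_{sero}_{cond}.tsv")
            mrna_sets[cond] = set(res.index[res.significant.fillna(False)])
            de_section[f"{sero}:{cond}:mrna"] = {
                "n_significant": int(res.significant.sum()),
                "n_tested": int(res.pvalue.notna().sum()),
                "target_significant": bool(
                    res.loc[TARGET_GENES[cond], "significant"]
                ),
            }
        if len(mrna_sets) >= 2:
            inter = diffexpr.de_set_intersections(
                mrna_sets, set(ds.mrna_counts.index)
            )
            de_section[f"{sero}:intersections:mrna"] = {
                "&".join(k): v for k, v in inter.items()
            }
    report["differential_expression"] = de_section
    log.info("differential expression done in %.1fs", time.monotonic() - t0)

    t0 = _stage("offtarget")
    ot_section = {}
    for cond, frag in ds.feeding_fragments.items():
        kmers = offtarget.enumerate_kmers(frag.sequence, k=config.offtarget_k)
        excluded = [frag.interval]
        hits = offtarget.scan_exact_matches(kmers, ds.genome, excluded)
        genes_hit = offtarget.map_hits_to_genes(hits, ds.genes)
        entry = {
            "n_kmers": len(kmers),
            "n_hits": len(hits),
            "offtarget_genes": genes_hit,
        }
        if config.offtarget_seed_mode:
            seed_hits = offtarget.seed_match_scan(kmers, ds.genome, excluded)
            entry["n_seed_hits"] = len(seed_hits)
        ot_section[cond] = entry
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(
            outdir / f"offtarget_{cond}.tsv", sep="\t", index=False
        )
    report["offtarget"] = ot_section
    log.info("offtarget done in %.1fs", time.monotonic() - t0)

    t0 = _stage("stats")
    # knockdown efficiency from TPM with feeding-region exclusion
    kd_section = {}
    gene_lengths = pd.Series(
        (ds.genes.end - ds.genes.start).to_numpy(), index=ds.genes.gene_id, dtype=float
    )
    cond_by_lib = {l.library_id: l.condition for l in config.simulation.library_design}
    efflens = pd.DataFrame(
        {lib: gene_lengths.copy() for lib in ds.mrna_counts.columns}
    )
    for lib in ds.mrna_counts.columns:
        cond = cond_by_lib[lib]
        if cond in ds.feeding_fragments:
            gene_id, fa, fb = _fragment_transcript_span(ds, cond)
            model = stats.TranscriptModel(gene_id, int(gene_lengths[gene_id]))
            model = stats.exclude_feeding_region(model, fa, fb, pad=config.feeding_pad)
            efflens.loc[gene_id, lib] = model.effective_length
    tpm = stats.tpm_matrix(ds.mrna_counts, efflens)
    io.write_tsv(tpm, outdir / "mrna_tpm.tsv")
    for sero in serotypes:
        sero_meta = meta[meta.serotype == sero]
        tpm_cond = stats.condition_means(tpm[list(sero_meta.library_id)], sero_meta)
        for cond, gene_id in TARGET_GENES.items():
            if cond not in tpm_cond.columns or "WT" not in tpm_cond.columns:
                continue
            fc, reduction = stats.knockdown_efficiency(
                float(tpm_cond.loc[gene_id, cond]), float(tpm_cond.loc[gene_id, "WT"])
            )
            kd_section[f"{sero}:{cond}"] = {
                "gene": gene_id,
                "fold_change": fc,
                "reduction": reduction,
            }
    report["knockdown_efficiency"] = kd_section

    abundance, phasing_section, clustering_section = {}, {}, {}
    phased = ds.loci.set_index("locus_id").phased
    for sero in serotypes:
        sero_meta = meta[meta.serotype == sero]
        sero_norm = normalized[list(sero_meta.library_id)]
        cond_means = stats.condition_means(sero_norm, sero_meta)
        for cond in ("ND169_KD", "DCR1_KD"):
            if cond not in cond_means.columns:
                continue
            abundance[f"{sero}:{cond}"] = {
                "median_wt": float(cond_means["WT"].median()),
                "median_kd": float(cond_means[cond].median()),
                "wilcoxon_p": stats.wilcoxon_compare(
                    cond_means[cond], cond_means["WT"]
                ),
            }
            fcp = stats.fold_change_by_phasing(
                cond_means[cond], cond_means["WT"], phased, config.pseudocount
            )
            phasing_section[f"{sero}:{cond}"] = {
                "median_log2fc_phased": fcp["median_phased"],
                "median_log2fc_unphased": fcp["median_unphased"],
                "wilcoxon_p": fcp["pvalue"],
                "n_phased": int(len(fcp["phased"])),
                "n_unphased": int(len(fcp["unphased"])),
            }
        linkage, labels = stats.hierarchical_clustering(sero_norm)
        (outdir / f"dendrogram_{sero}.nwk").write_text(
            stats.to_newick(linkage, labels) + "\n"
        )
        wt_libs = set(sero_meta.loc[sero_meta.condition == "WT", "library_id"])
        clustering_section[sero] = {
            "wt_exclusive_clade": bool(
                stats.forms_exclusive_clade(linkage, labels, wt_libs)
            ),
            "n_libraries": len(labels),
        }
    report["abundance_comparison"] = abundance
    report["phasing"] = phasing_section
    report["clustering"] = clustering_section
    log.info("stats done in %.1fs", time.monotonic() - t0)

    io.write_json(_round_floats(report), outdir / "report.json")
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["simulation"]["library_design"] = [
        list(map(str, (l.library_id, l.serotype, l.condition, l.replicate)))
        for l in config.simulation.library_design
    ]
    return d


def _round_floats(obj, digits: int = 8):
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
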