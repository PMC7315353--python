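import dataclasses

import numpy as np
import pandas as pd
import pytest

from exofeed.simulate import (
    SimulationConfig,
    generate_genome_and_annotation,
    simulate_dataset,
    simulate_mrna_counts,
    simulate_sirna_counts,
    target_effective_fraction,
)
from exofeed.stats import compute_tpm, knockdown_efficiency

from conftest import three_vs_three


def _mini(**kw) -> SimulationConfig:
    base = dict(
        seed=7,
        n_scaffolds=2,
        scaffold_length=120_000,
        n_loci=60,
        n_free_genes=5,
        n_background_loci=10,
        depth=30_000,
        library_design=three_vs_three(),
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenomeGeneration:
    def test_scaffold_count_and_length(self):
        ds = generate_genome_and_annotation(_mini(n_scaffolds=2, scaffold_length=50_000, n_loci=20, n_free_genes=2, n_background_loci=2))
        assert len(ds.genome) == 2
        assert all(len(seq) == 50_000 for seq in ds.genome.values())
        assert set("".join(ds.genome.values())) <= set("ACGT")

    def test_phased_flag_count_matches_requested_fraction(self):
        ds = generate_genome_and_annotation(
            _mini(n_loci=200, phased_fraction=0.1, scaffold_length=250_000)
        )
        assert len(ds.loci) == 200
        assert int(ds.loci.phased.sum()) == 20

    def test_features_fit_inside_genome_and_genes(self):
        ds = generate_genome_and_annotation(_mini())
        genes = ds.genes.set_index("gene_id")
        for locus in ds.loci.itertuples():
            host = genes.loc[locus.host_gene]
            assert host.scaffold == locus.scaffold
            assert host.start <= locus.start < locus.end <= host.end
        for g in ds.genes.itertuples():
            assert g.end <= len(ds.genome[g.scaffold])
        # genes never overlap (so locus counting is unambiguous)
        for scaffold, grp in ds.genes.groupby("scaffold"):
            srt = grp.sort_values("start")
            assert (srt.start.to_numpy()[1:] >= srt.end.to_numpy()[:-1]).all()

    def test_feeding_fragments_copied_verbatim_from_genome(self):
        ds = generate_genome_and_annotation(_mini())
        for frag in ds.feeding_fragments.values():
            iv = frag.interval
            assert frag.sequence == ds.genome[iv.scaffold][iv.start : iv.end]
            assert len(frag.sequence) >= 200

    def test_oversized_request_raises_sizing_error(self):
        with pytest.raises(ValueError, match="genome provides"):
            generate_genome_and_annotation(_mini(n_loci=5_000))

    def test_same_seed_reproduces_identical_dataset(self):
        a = simulate_dataset(_mini())
        b = simulate_dataset(_mini())
        assert a.genome == b.genome
        pd.testing.assert_frame_equal(a.loci, b.loci)
        pd.testing.assert_frame_equal(a.sirna_counts, b.sirna_counts)
        pd.testing.assert_frame_equal(a.mrna_counts, b.mrna_counts)
        pd.testing.assert_frame_equal(a.library_meta, b.library_meta)


class TestSirnaCounts:
    def test_totals_conserve_read_categories(self):
        ds = simulate_dataset(_mini())
        meta = ds.library_meta.set_index("library_id")
        for lib in meta.index:
            expected = (
                meta.loc[lib, "K"]
                + ds.sirna_counts[lib].sum()
                + ds.background_counts[lib].sum()
            )
            assert meta.loc[lib, "T"] == expected
            assert meta.loc[lib, "K"] <= meta.loc[lib, "T"]
        assert (meta.loc[meta.condition == "WT", "K"] == 0).all()

    def test_null_depletion_gives_unit_mean_ratio(self):
        cfg = _mini(
            n_loci=1_000,
            locus_depletion=1.0,
            phased_extra_depletion=1.0,
            depth=2_000_000,
            scaffold_length=900_000,
        )
        ds = generate_genome_and_annotation(cfg)
        sirna, _, meta, _ = simulate_sirna_counts(cfg, ds.loci, ds.background_loci)
        meta = meta.set_index("library_id")
        wt = sirna[meta.index[meta.condition == "WT"]]
        kd = sirna[meta.index[meta.condition != "WT"]]
        # per-locus share of the non-feeding pool should be unchanged
        share_wt = wt.sum(axis=1) / (meta.loc[wt.columns, "T"]).sum()
        tk = (meta.loc[kd.columns, "T"] - meta.loc[kd.columns, "K"]).sum()
        share_kd = kd.sum(axis=1) / tk
        ratio = share_kd / share_wt
        assert abs(float(np.median(ratio)) - 1.0) < 0.03

    def test_half_depletion_recovered_in_locus_shares(self):
        cfg = _mini(
            n_loci=500,
            locus_depletion=0.5,
            phased_fraction=0.0,
            depth=2_000_000,
            scaffold_length=500_000,
        )
        ds = generate_genome_and_annotation(cfg)
        sirna, _, meta, _ = simulate_sirna_counts(cfg, ds.loci, ds.background_loci)
        meta = meta.set_index("library_id")
        share = sirna / (meta["T"] - meta["K"])
        wt = share[meta.index[meta.condition == "WT"]].mean(axis=1)
        kd = share[meta.index[meta.condition != "WT"]].mean(axis=1)
        assert 0.45 <= float((kd / wt).median()) <= 0.55

    def test_zero_dispersion_is_poisson_limit(self):
        libs = tuple(
            dataclasses.replace(l, library_id=f"wt{i}", replicate=i)
            for i, l in enumerate(three_vs_three()[:1] * 40, start=1)
        )
        cfg = _mini(nb_dispersion=0.0, library_design=libs, n_loci=200, scaffold_length=250_000, depth=200_000)
        ds = generate_genome_and_annotation(cfg)
        sirna, _, _, _ = simulate_sirna_counts(cfg, ds.loci, ds.background_loci)
        mean = sirna.mean(axis=1)
        var = sirna.var(axis=1, ddof=1)
        # index of dispersion concentrates at 1 for Poisson
        assert abs(float((var / mean).median()) - 1.0) < 0.15

    def test_truth_records_phased_extra_depletion(self):
        cfg = _mini(phased_fraction=0.2, locus_depletion=0.5, phased_extra_depletion=0.5)
        ds = generate_genome_and_annotation(cfg)
        _, _, _, truth = simulate_sirna_counts(cfg, ds.loci, ds.background_loci)
        fc = truth["locus_fold_change"]
        phased = ds.loci.set_index("locus_id").phased
        assert (fc.loc[phased, "DCR1_KD"] == 0.25).all()
        assert (fc.loc[~phased, "DCR1_KD"] == 0.5).all()
        assert (fc.loc[phased, "ND169_KD"] == 0.5).all()
        assert (fc["WT"] == 1.0).all()


class TestMrnaCounts:
    def test_knockdown_recovered_from_effective_length_tpm(self):
        cfg = _mini(mrna_knockdown_fc=0.02, mrna_global_fc=1.0)
        ds = generate_genome_and_annotation(cfg)
        mrna, _ = simulate_mrna_counts(cfg, ds.genes)
        meta = pd.DataFrame(
            [(l.library_id, l.condition) for l in cfg.library_design],
            columns=["library_id", "condition"],
        ).set_index("library_id")
        lengths = pd.Series(
            float(cfg.gene_length), index=ds.genes.gene_id
        )
        eff = lengths.copy()
        eff["ND169"] = cfg.gene_length * target_effective_fraction(cfg)
        wt_libs = meta.index[meta.condition == "WT"]
        kd_libs = meta.index[meta.condition == "ND169_KD"]
        tpm_wt = compute_tpm(mrna[wt_libs].mean(axis=1), lengths)
        tpm_kd = compute_tpm(mrna[kd_libs].mean(axis=1), eff)
        fc, reduction = knockdown_efficiency(tpm_kd["ND169"], tpm_wt["ND169"])
        assert 0.01 <= fc <= 0.04
        assert reduction > 0.95

    def test_global_null_median_fold_change_near_one(self):
        cfg = _mini(mrna_global_fc=1.0)
        ds = generate_genome_and_annotation(cfg)
        mrna, _ = simulate_mrna_counts(cfg, ds.genes)
        meta = {l.library_id: l.condition for l in cfg.library_design}
        wt = mrna[[k for k, v in meta.items() if v == "WT"]].mean(axis=1)
        kd = mrna[[k for k, v in meta.items() if v == "ND169_KD"]].mean(axis=1)
        ratio = (kd / wt).drop(index=["ND169", "DCR1"])
        assert abs(float(ratio.median()) - 1.0) < 0.1

    def test_unknocked_target_not_flagged_by_de(self):
        from exofeed.diffexpr import run_de

        hits = 0
        for seed in range(20):
            cfg = _mini(
                seed=100 + seed,
                mrna_knockdown_fc=1.0,
                mrna_region_filtered=False,
            )
            ds = generate_genome_and_annotation(cfg)
            mrna, _ = simulate_mrna_counts(cfg, ds.genes)
            meta = pd.DataFrame(
                [(l.library_id, "51A", l.condition) for l in cfg.library_design],
                columns=["library_id", "serotype", "condition"],
            )
            res = run_de(mrna, meta, "ND169_KD")
            hits += bool(res.loc["ND169", "significant"])
        assert hits <= 2  # not significant in >= 90% of seeds
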