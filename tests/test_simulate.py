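import numpy as np
import pandas as pd
import pytest

from cooccmap import (
    SimulationConfig,
    VennDesign,
    bd_reduced_genes,
    call_bd,
    differential_breadth,
    element_mean_methylation,
    gene_binding_sets,
    measure_domains,
    simulate_annotation,
    simulate_chromatin,
    simulate_methylome,
    simulate_tcr,
)
from cooccmap.tcr import ChainRecord, call_clonotypes, clonal_overlap, expansion_density


def small_config(**overrides):
    base = dict(
        seed=11,
        n_genes=300,
        n_chroms=2,
        chrom_length=6_500_000,
        cooccupancy_design=VennDesign(
            abc=7, ab_only=20, ac_only=0, bc_only=1, a_only=30, b_only=20, c_only=0
        ),
        meth_n_cpgs=3000,
        n_cells=600,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestSimulateAnnotation:
    def test_deterministic(self):
        cfg = small_config()
        a1 = simulate_annotation(cfg)
        a2 = simulate_annotation(cfg)
        assert [
            (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end) for g in a1.genes
        ] == [(g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end) for g in a2.genes]

    def test_empty(self):
        ann = simulate_annotation(small_config(n_genes=0))
        assert len(ann) == 0

    def test_spacing_brute_force(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.tx_start)
            for a, b in zip(genes, genes[1:]):
                assert b.tx_start - a.tx_end >= 2 * cfg.gene_margin

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            simulate_annotation(small_config(chrom_length=1_000_000))


@pytest.fixture(scope="module")
def sim():
    cfg = small_config()
    ann = simulate_annotation(cfg)
    return simulate_chromatin(cfg, ann)


@pytest.fixture(scope="module")
def msim():
    cfg = small_config()
    return simulate_methylome(cfg, simulate_annotation(cfg))


class TestSimulateChromatin:

    def test_deterministic(self, sim):
        cfg = small_config()
        sim2 = simulate_chromatin(cfg, simulate_annotation(cfg))
        for name in sim.fragments:
            assert sim.fragments[name].equals(sim2.fragments[name])
        assert sim.truth.equals(sim2.truth)

    def test_design_exceeding_domains_raises(self):
        cfg = small_config(
            cooccupancy_design=VennDesign(abc=200, bc_only=50),
        )
        ann = simulate_annotation(cfg)
        with pytest.raises(ValueError, match="design"):
            simulate_chromatin(cfg, ann)

    def test_truth_matches_files_binding_flags(self, sim):
        sets = gene_binding_sets(
            sim.peaks["foxp3"], sim.peaks["cxxc1"], sim.peaks["k4me3_wt"],
            sim.annotation,
        )
        truth = sim.truth.set_index("gene_id")
        assert sets["foxp3_bound"].equals(truth["foxp3_bound"])
        assert sets["cxxc1_bound"].equals(truth["cxxc1_bound"])
        assert sets["k4me3_enriched"].equals(truth["has_domain"])

    def test_truth_matches_files_domains(self, sim):
        domains = measure_domains(sim.peaks["k4me3_wt"], sim.annotation)
        call_bd(domains)
        truth = sim.truth.set_index("gene_id")
        assert len(domains) == int(truth["has_domain"].sum())
        for d in domains:
            assert d.width == truth.loc[d.gene_id, "width"]
            assert d.is_bd == truth.loc[d.gene_id, "planted_bd"]

    def test_zero_ko_effect_gives_zero_reduced(self):
        cfg = small_config(ko_reduction=0.0)
        ann = simulate_annotation(cfg)
        sim = simulate_chromatin(cfg, ann)
        domains = measure_domains(sim.peaks["k4me3_wt"], ann)
        call_bd(domains)
        diff = differential_breadth(
            domains,
            sim.fragments["k4me3_wt"], sim.totals["k4me3_wt"],
            sim.fragments["k4me3_ko"], sim.totals["k4me3_ko"],
        )
        assert sum(r.reduced for r in diff) == 0
        assert bd_reduced_genes(domains, diff) == set()


class TestSimulateMethylome:
    def test_deterministic(self, msim):
        cfg = small_config()
        again = simulate_methylome(cfg, simulate_annotation(cfg))
        assert msim.calls.equals(again.calls)

    def test_estimator_recovers_expected_class_means(self, msim):
        frame = msim.calls.rename(columns={"start": "pos"})
        frame["total"] = frame["meth"] + frame["unmeth"]
        table = element_mean_methylation(
            frame[["chrom", "pos", "meth", "total"]], msim.elements
        ).set_index("class")
        for klass, (n_expected, mean_expected) in msim.class_expected.items():
            assert table.loc[klass, "n_cpgs"] == n_expected
            if n_expected >= 100:
                assert table.loc[klass, "mean_level"] == pytest.approx(
                    mean_expected, abs=0.03
                )

    def test_pure_classes_match_generating_means(self, msim):
        cfg = msim.config
        for klass in ("promoter", "cgi", "repeats"):
            n, expected = msim.class_expected[klass]
            assert expected == pytest.approx(cfg.methylation_means[klass], abs=1e-9)

    def test_zero_dispersion_concentrates(self):
        cfg = small_config(meth_dispersion=0.0, meth_depth=200, meth_n_cpgs=2000)
        msim = simulate_methylome(cfg, simulate_annotation(cfg))
        truth = msim.truth
        levels = msim.calls["meth"].to_numpy() / cfg.meth_depth
        mu = truth["mu"].to_numpy()
        # binomial-only noise at depth 200: levels hug the planted means
        assert np.abs(levels - mu).mean() < 0.05


class TestSimulateTcr:
    def test_deterministic(self):
        cfg = small_config()
        t1, t2 = simulate_tcr(cfg), simulate_tcr(cfg)
        assert t1.contigs.equals(t2.contigs)

    def test_zero_sharing_gives_zero_off_diagonal(self):
        cfg = small_config(sharing_rate=0.0)
        tsim = simulate_tcr(cfg)
        chains = [
            ChainRecord(r.cell_id, r.locus, r.cdr3_nt, int(r.umi_count))
            for r in tsim.contigs.itertuples(index=False)
        ]
        cells = call_clonotypes(
            chains, dict(zip(tsim.clusters["cell_id"], tsim.clusters["cluster"]))
        )
        m = clonal_overlap(cells, expanded_only=True)
        off = m.to_numpy()[~np.eye(len(m), dtype=bool)]
        assert np.all(off == 0)

    def test_planted_expansion_fraction_recovered(self):
        cfg = small_config()
        tsim = simulate_tcr(cfg)
        chains = [
            ChainRecord(r.cell_id, r.locus, r.cdr3_nt, int(r.umi_count))
            for r in tsim.contigs.itertuples(index=False)
        ]
        cells = call_clonotypes(
            chains, dict(zip(tsim.clusters["cell_id"], tsim.clusters["cluster"]))
        )
        density = expansion_density(cells).set_index("cluster")
        for cname, planted in tsim.truth["planted_fraction"].items():
            assert density.loc[cname, "expanded_fraction"] >= planted - 1e-9
            assert density.loc[cname, "expanded_fraction"] == pytest.approx(
                planted, abs=0.05
            )
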