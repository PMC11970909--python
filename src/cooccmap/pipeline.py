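"""End-to-end demo pipeline: simulate -> quantify -> states -> breadth ->
co-occupancy -> methylome -> TCR, with every input and output written as
plain text. Running it twice with the same config produces byte-identical
files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io
from .breadth import (
    bd_reduced_genes,
    call_bd,
    classify_domains,
    differential_breadth,
    differential_table,
    domain_table,
    measure_domains,
)
from .cooccupancy import cooccupancy_fraction, gene_binding_sets, venn_counts
from .genome import classify_genomic_regions
from .intervals import intersect_sets
from .methylation import element_mean_methylation
from .quantify import quantify_promoters
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_chromatin,
    simulate_methylome,
    simulate_tcr,
)
from .states import cluster_promoters, state_expression_summary
from .tcr import (
    ChainRecord,
    call_clonotypes,
    clonal_overlap,
    expansion_density,
)

__all__ = ["run_demo"]

_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, **kwargs)


def run_demo(config: SimulationConfig | None = None, out_dir: str | Path = "demo_out") -> dict:
    """Simulate a full dataset and run every analysis stage over it.

    Writes inputs under ``<out_dir>/inputs`` and results under
    ``<out_dir>/results``; returns a dict with the key result tables.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    # --- simulate
    annotation = simulate_annotation(config)
    io.write_gene_table(annotation, inputs / "genes.tsv")
    io.write_chrom_sizes(annotation.chrom_sizes, inputs / "chrom.sizes")
    sim = simulate_chromatin(config, annotation)
    for name, peaks in sim.peaks.items():
        io.write_bed(peaks, inputs / f"peaks_{name}.bed")
    for name, frags in sim.fragments.items():
        io.write_bed(frags, inputs / f"fragments_{name}.bed")
    io.write_json(sim.totals, inputs / "library_totals.json")
    _write(sim.truth, inputs / "truth_genes.tsv")
    expr = pd.DataFrame(
        {"gene_id": list(sim.expression), "value": list(sim.expression.values())}
    )
    _write(expr, inputs / "expression.tsv")

    # --- promoter quantification and state clustering
    matrix = quantify_promoters(
        annotation,
        {"H3K4me3": sim.fragments["k4me3_wt"], "H3K27me3": sim.fragments["h3k27me3"]},
        totals={"H3K4me3": sim.totals["k4me3_wt"], "H3K27me3": sim.totals["h3k27me3"]},
        halfwidth=config.promoter_halfwidth,
    )
    matrix.to_tsv(results / "promoter_rpkm.tsv")
    fit = cluster_promoters(matrix, k=4, seed=config.seed)
    _write(fit.assignments(), results / "state_assignments.tsv")
    _write(fit.summary(), results / "state_summary.tsv")
    expr_summary = state_expression_summary(fit, sim.expression)
    _write(expr_summary, results / "state_expression.tsv")

    # --- genomic distribution of co-occupied peaks
    hit_idx = {i for i, _ in intersect_sets(sim.peaks["foxp3"], sim.peaks["k4me3_wt"])}
    overlap_peaks = [sim.peaks["foxp3"][i] for i in sorted(hit_idx)]
    if overlap_peaks:
        cats = classify_genomic_regions(overlap_peaks, annotation)
        dist = (
            pd.Series(cats).value_counts().rename_axis("category").reset_index(name="n_peaks")
        )
        _write(dist, results / "genomic_distribution.tsv")

    # --- breadth and differential signal
    domains = measure_domains(
        sim.peaks["k4me3_wt"], annotation, promoter_halfwidth=config.promoter_halfwidth
    )
    classify_domains(domains)
    call_bd(domains)
    _write(domain_table(domains), results / "domains.tsv")
    diff = differential_breadth(
        domains,
        sim.fragments["k4me3_wt"],
        sim.totals["k4me3_wt"],
        sim.fragments["k4me3_ko"],
        sim.totals["k4me3_ko"],
    )
    _write(differential_table(diff), results / "differential_breadth.tsv")
    reduced = bd_reduced_genes(domains, diff)

    # --- co-occupancy
    sets = gene_binding_sets(
        sim.peaks["foxp3"], sim.peaks["cxxc1"], sim.peaks["k4me3_wt"],
        annotation, bd_reduced=reduced,
    )
    sets.to_csv(results / "gene_binding_sets.tsv", sep="\t")
    venn = venn_counts(
        set(sets.index[sets["foxp3_bound"]]),
        set(sets.index[sets["cxxc1_bound"]]),
        reduced,
        set(sets.index),
    )
    _write(
        pd.DataFrame(sorted(venn.items()), columns=["region", "count"]),
        results / "venn_counts.tsv",
    )
    num, den, frac, pct = cooccupancy_fraction(
        sets, ["foxp3_bound"], ["cxxc1_bound", "bd_reduced"]
    )
    _write(
        pd.DataFrame(
            [{"numerator": num, "denominator": den, "fraction": frac, "percent": pct}]
        ),
        results / "cooccupancy_fraction.tsv",
    )

    # --- methylome
    meth = simulate_methylome(config, annotation)
    meth.calls.to_csv(
        inputs / "cpg_calls.tsv", sep="\t", index=False, header=False
    )
    for klass, ivs in meth.elements.items():
        if ivs:
            io.write_bed(
                [iv for iv in ivs], inputs / f"elements_{klass}.bed"
            )
    meth_summary = element_mean_methylation(meth.calls.rename(
        columns={"start": "pos", "meth": "meth", "unmeth": "unmeth"}
    ).assign(total=lambda d: d["meth"] + d["unmeth"])[["chrom", "pos", "meth", "total"]],
        meth.elements,
    )
    _write(meth_summary, results / "methylation_by_element.tsv")

    # --- TCR repertoire
    tcr_sim = simulate_tcr(config)
    tcr_sim.contigs.to_csv(inputs / "tcr_contigs.csv", index=False)
    _write(tcr_sim.clusters, inputs / "tcr_clusters.tsv")
    chains = [
        ChainRecord(r.cell_id, r.locus, r.cdr3_nt, int(r.umi_count))
        for r in tcr_sim.contigs.itertuples(index=False)
    ]
    cells = call_clonotypes(
        chains, dict(zip(tcr_sim.clusters["cell_id"], tcr_sim.clusters["cluster"]))
    )
    density = expansion_density(cells)
    _write(density, results / "tcr_expansion.tsv")
    overlap = clonal_overlap(cells, expanded_only=True)
    overlap.to_csv(results / "tcr_overlap.tsv", sep="\t", float_format=_FLOAT_FMT)

    return {
        "annotation": annotation,
        "matrix": matrix,
        "states": fit,
        "state_expression": expr_summary,
        "domains": domains,
        "differential": diff,
        "bd_reduced": reduced,
        "binding_sets": sets,
        "venn": venn,
        "cooccupancy": (num, den, frac, pct),
        "methylation": meth_summary,
        "methylome_sim": meth,
        "tcr_density": density,
        "tcr_overlap": overlap,
        "chromatin_sim": sim,
    }
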