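"""Synthetic-data generation with planted ground truth.

Every input the pipeline consumes can be generated here: a gene annotation,
peak and fragment sets for FOXP3 / CXXC1 / H3K4me3 (WT and KO) / H3K27me3,
a per-CpG methylome, and a single-cell TCR contig table. Planted truths
(chromatin state, domain width and class, binding flags, KO-reduced flag,
per-CpG methylation means, clone sizes) are recorded alongside so every
analysis stage can be checked against what was planted.

Statistical structure: four promoter states with distinct H3K4me3/H3K27me3
Poisson fragment rates; a narrow/medium/broad mixture of domain widths; a
designed three-way gene-set overlap (FOXP3 x CXXC1 x BD-reduced); a
fractional KO signal reduction inside designated broad domains; per-element
Beta-Binomial methylation; and a heavy-tailed (shifted-geometric) clone-size
distribution with cross-cluster clonotype sharing.

All generators are pure functions of the configuration (which carries the
seed): identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAnnotation
from .intervals import Interval
from .methylation import ELEMENT_CLASSES, _membership
from .states import STATE_LABELS

__all__ = [
    "VennDesign",
    "SimulationConfig",
    "ChromatinSim",
    "MethylomeSim",
    "TcrSim",
    "simulate_annotation",
    "simulate_chromatin",
    "simulate_methylome",
    "simulate_tcr",
    "cooccupancy_benchmark_config",
]

# gene-internal layout, as offsets from the TSS along the direction of
# transcription (synthetic geometry: fixed-size UTR/exon/intron segments so
# element-level methylation means are identifiable)
_UTR5 = (2000, 2400)
_CDS = (2400, 3600)
_INTRON = (3600, 5200)
_UTR3 = (5200, 5600)
_FLANK_FROM = 5600


@dataclass
class VennDesign:
    """Target cardinalities for the three-way gene-set overlap.

    A = FOXP3-bound, B = CXXC1-bound, C = BD-reduced. Region names follow
    :func:`cooccmap.cooccupancy.venn_counts`. The default scales the designed
    B-and-C composition so that 47/49 of CXXC1-bound BD-reduced genes are
    also FOXP3-bound (96%).
    """

    abc: int = 47
    ab_only: int = 120
    ac_only: int = 0
    bc_only: int = 2
    a_only: int = 250
    b_only: int = 150
    c_only: int = 0

    @property
    def size_c(self) -> int:
        return self.abc + self.ac_only + self.bc_only + self.c_only

    def total_designed(self) -> int:
        return (
            self.abc + self.ab_only + self.ac_only + self.bc_only
            + self.a_only + self.b_only + self.c_only
        )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator, with the demo defaults."""

    seed: int = 0

    # genome / annotation
    n_genes: int = 2000
    n_chroms: int = 4
    chrom_length: int = 25_000_000
    gene_length_range: tuple[int, int] = (6000, 12000)
    gene_margin: int = 12_000  # clear bp kept on each side of every gene

    # chromatin states (order follows STATE_LABELS)
    state_proportions: tuple[float, ...] = (0.30, 0.30, 0.20, 0.20)
    k4_promoter_rates: tuple[float, ...] = (800.0, 300.0, 4.0, 4.0)
    k27_promoter_rates: tuple[float, ...] = (10.0, 10.0, 400.0, 4.0)
    k4_flank_rate_per_kb: float = 100.0
    fragment_length: int = 200
    promoter_halfwidth: int = 2000

    # domain widths
    breadth_proportions: tuple[float, float, float] = (0.25, 0.60, 0.15)
    width_ranges: dict = field(
        default_factory=lambda: {
            "narrow": (200, 999),
            "medium": (1000, 5000),
            "broad": (5001, 12000),
            "designed_bd": (14000, 20000),
        }
    )

    # genotype effect
    ko_reduction: float = 0.6
    ko_bd_fraction: float = 0.2  # used when no co-occupancy design is given

    # co-occupancy design (None -> random binding via the fractions below)
    cooccupancy_design: VennDesign | None = field(default_factory=VennDesign)
    foxp3_gene_fraction: float = 0.30
    cxxc1_gene_fraction: float = 0.25
    n_background_peaks: int = 50
    background_peak_width: int = 300

    # expression linked to states
    expression_means: tuple[float, ...] = (100.0, 50.0, 5.0, 2.0)
    expression_sigma: float = 0.5

    # methylome
    meth_n_cpgs: int = 10_000
    meth_depth: int = 30
    meth_dispersion: float = 0.05
    methylation_means: dict = field(
        default_factory=lambda: {
            "promoter": 0.10,
            "utr5": 0.25,
            "exon": 0.80,
            "intron": 0.72,
            "utr3": 0.65,
            "genebody": 0.75,
            "intergenic": 0.80,
            "cgi": 0.05,
            "repeats": 0.85,
        }
    )
    meth_class_proportions: dict = field(
        default_factory=lambda: {
            "promoter": 0.15,
            "utr5": 0.05,
            "exon": 0.15,
            "intron": 0.20,
            "utr3": 0.05,
            "genebody": 0.10,
            "intergenic": 0.15,
            "cgi": 0.08,
            "repeats": 0.07,
        }
    )

    # TCR repertoire
    n_cells: int = 2000
    tcr_cluster_proportions: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    expansion_fraction: float = 0.4
    clone_geometric_p: float = 0.5
    sharing_rate: float = 0.15
    cdr3_length: int = 15
    umi_range: tuple[int, int] = (5, 50)
    decoy_chain_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name, props in (
            ("state_proportions", self.state_proportions),
            ("tcr_cluster_proportions", self.tcr_cluster_proportions),
        ):
            if abs(sum(props) - 1.0) > 1e-9 or any(
                not 0 < p < 1 for p in props
            ):
                raise ValueError(f"{name} must lie in (0,1) and sum to 1")
        if abs(sum(self.breadth_proportions) - 1.0) > 1e-9:
            raise ValueError("breadth_proportions must sum to 1")
        if not 0 <= self.ko_reduction < 1:
            raise ValueError("ko_reduction must be in [0, 1)")
        if self.meth_depth < 1 or self.meth_n_cpgs < 0:
            raise ValueError("methylome depth/size must be positive")
        if not 0 <= self.meth_dispersion < 1:
            raise ValueError("meth_dispersion must be in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("cooccupancy_design") is not None:
            raw["cooccupancy_design"] = VennDesign(**raw["cooccupancy_design"])
        for key in (
            "gene_length_range", "state_proportions", "k4_promoter_rates",
            "k27_promoter_rates", "breadth_proportions", "expression_means",
            "tcr_cluster_proportions", "umi_range",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "width_ranges" in raw:
            raw["width_ranges"] = {
                k: tuple(v) for k, v in raw["width_ranges"].items()
            }
        return cls(**raw)


def cooccupancy_benchmark_config(seed: int = 0) -> SimulationConfig:
    """Full-scale co-occupancy design: 294 CXXC1-bound BD-reduced genes of
    which 283 are also FOXP3-bound (96%), with enough H3K4me3 domains that
    the designed genes fit inside the top-5% breadth cut."""
    return SimulationConfig(
        seed=seed,
        n_genes=7500,
        chrom_length=80_000_000,
        state_proportions=(0.42, 0.40, 0.09, 0.09),
        cooccupancy_design=VennDesign(
            abc=283, ab_only=400, ac_only=0, bc_only=11,
            a_only=900, b_only=500, c_only=0,
        ),
    )


def _apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of n items over proportions."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with random strands and a guaranteed
    clear margin on each side (slot-based placement)."""
    rng = np.random.default_rng([config.seed, 11])
    l_lo, l_hi = config.gene_length_range
    if l_hi < _FLANK_FROM + 400:
        raise ValueError("gene_length_range too short for the element layout")
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    if config.n_genes == 0:
        return GenomeAnnotation(genes=[], chrom_sizes=sizes)
    per_chrom = _apportion(config.n_genes, [1 / config.n_chroms] * config.n_chroms)
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(sizes):
        count = int(per_chrom[ci])
        if count == 0:
            continue
        slot = config.chrom_length // count
        if slot < l_hi + 2 * config.gene_margin:
            raise ValueError(
                "infeasible gene packing: increase chrom_length or reduce "
                "n_genes/gene_margin"
            )
        for si in range(count):
            length = int(rng.integers(l_lo, l_hi + 1))
            jitter_max = slot - length - 2 * config.gene_margin
            start = (
                si * slot + config.gene_margin + int(rng.integers(0, jitter_max + 1))
            )
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [
                _segment_abs(chrom, strand, start, start + length, seg)
                for seg in (_UTR5, _CDS, _UTR3)
            ]
            exons.sort(key=lambda iv: iv.start)
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:05d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=start + length,
                    exons=exons,
                )
            )
            gi += 1
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def _segment_abs(
    chrom: str, strand: str, tx_start: int, tx_end: int, seg: tuple[int, int]
) -> Interval:
    """Map a (from-TSS, along-transcription) offset segment to coordinates."""
    d1, d2 = seg
    if strand == "+":
        return Interval(chrom, tx_start + d1, tx_start + d2)
    return Interval(chrom, tx_end - d2, tx_end - d1)


def gene_layout(gene: GeneModel) -> dict[str, Interval]:
    """The synthetic within-gene element segments of a simulated gene."""
    args = (gene.chrom, gene.strand, gene.tx_start, gene.tx_end)
    return {
        "utr5": _segment_abs(*args, _UTR5),
        "exon": _segment_abs(*args, _CDS),
        "intron": _segment_abs(*args, _INTRON),
        "utr3": _segment_abs(*args, _UTR3),
        "flank": _segment_abs(*args, (_FLANK_FROM, gene.tx_end - gene.tx_start)),
    }


@dataclass
class ChromatinSim:
    """Planted chromatin landscape: peaks, fragment libraries and truth."""

    annotation: GenomeAnnotation
    peaks: dict[str, list[Interval]]
    fragments: dict[str, pd.DataFrame]
    totals: dict[str, int]
    truth: pd.DataFrame
    expression: dict[str, float]
    config: SimulationConfig


def _uniform_fragments(
    rng: np.random.Generator,
    chroms: np.ndarray,
    seg_starts: np.ndarray,
    seg_ends: np.ndarray,
    counts: np.ndarray,
    frag_len: int,
) -> pd.DataFrame:
    """Place Poisson-count fragments uniformly inside per-gene segments."""
    keep = counts > 0
    chroms, starts, ends, counts = (
        chroms[keep], seg_starts[keep], seg_ends[keep], counts[keep],
    )
    rep_chrom = np.repeat(chroms, counts)
    lo = np.repeat(starts, counts)
    hi = np.maximum(lo + 1, np.repeat(ends, counts) - frag_len)
    frag_starts = rng.integers(lo, hi)
    return pd.DataFrame(
        {"chrom": rep_chrom, "start": frag_starts, "end": frag_starts + frag_len}
    )


def _background_positions(
    annotation: GenomeAnnotation, clearance: int
) -> list[tuple[str, int]]:
    """Midpoints of inter-gene gaps far from every gene and promoter."""
    out = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: g.tx_start)
        for a, b in zip(genes, genes[1:]):
            gap = b.tx_start - a.tx_end
            mid = a.tx_end + gap // 2
            if gap // 2 >= clearance:
                out.append((chrom, mid))
    return out


def _planted_bd_flags(
    widths: dict[str, int], annotation: GenomeAnnotation, fraction: float = 0.05
) -> set[str]:
    """Top-``fraction`` widest planted domains, same tie-break as call_bd."""
    gene_pos = {g.gene_id: (g.chrom, g.tss) for g in annotation.genes}
    order = sorted(
        widths, key=lambda gid: (-widths[gid], gene_pos[gid][0], gene_pos[gid][1])
    )
    n_bd = math.ceil(fraction * len(widths))
    return set(order[:n_bd])


def simulate_chromatin(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> ChromatinSim:
    """Generate peaks, fragments and ground truth for the chromatin stages."""
    rng = np.random.default_rng([config.seed, 23])
    n = len(annotation.genes)
    genes = annotation.genes
    empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
    if n == 0:
        return ChromatinSim(
            annotation, {}, {}, {}, pd.DataFrame(), {}, config
        )

    # --- states by exact apportionment of the configured proportions
    state_counts = _apportion(n, config.state_proportions)
    states = rng.permutation(np.repeat(np.arange(4), state_counts))
    domain_idx = np.flatnonzero(states <= 1)  # K4-high genes carry domains
    n_dom = domain_idx.size

    # --- co-occupancy design: memberships and the KO-affected gene set
    design = config.cooccupancy_design
    foxp3_genes: set[int] = set()
    cxxc1_genes: set[int] = set()
    designed_c: list[int] = []
    if design is not None:
        n_bd_callable = math.ceil(0.05 * n_dom) if n_dom else 0
        if design.size_c > n_bd_callable:
            raise ValueError(
                f"Venn design needs {design.size_c} BD-reduced genes but only "
                f"{n_bd_callable} broad domains are callable; increase n_genes "
                f"or the K4-high state proportions"
            )
        if design.total_designed() > n:
            raise ValueError("Venn design exceeds the number of genes")
        designed_c = list(rng.choice(domain_idx, design.size_c, replace=False))
        perm_c = rng.permutation(designed_c)
        cuts = np.cumsum([design.abc, design.ac_only, design.bc_only])
        c_abc, c_ac, c_bc, _ = np.split(perm_c, cuts)
        others = np.setdiff1d(np.arange(n), np.array(designed_c, dtype=int))
        perm_o = rng.permutation(others)
        cuts_o = np.cumsum([design.ab_only, design.a_only, design.b_only])
        o_ab, o_a, o_b, _ = np.split(perm_o, cuts_o)
        foxp3_genes = set(c_abc) | set(c_ac) | set(o_ab) | set(o_a)
        cxxc1_genes = set(c_abc) | set(c_bc) | set(o_ab) | set(o_b)
    else:
        foxp3_genes = set(
            rng.choice(n, int(round(config.foxp3_gene_fraction * n)), replace=False)
        )
        cxxc1_genes = set(
            rng.choice(n, int(round(config.cxxc1_gene_fraction * n)), replace=False)
        )

    # --- domain widths: class-conditional mixtures; designed BD-reduced
    # genes take the widest range so they always clear the top-5% cut
    widths: dict[str, int] = {}
    klass_planted: dict[str, str] = {}
    designed_set = set(int(i) for i in designed_c)
    non_designed = [int(i) for i in domain_idx if int(i) not in designed_set]
    class_names = ("narrow", "medium", "broad")
    class_draw = rng.choice(3, size=len(non_designed), p=config.breadth_proportions)
    for gi_loc, cls_i in zip(non_designed, class_draw):
        lo, hi = config.width_ranges[class_names[cls_i]]
        widths[genes[gi_loc].gene_id] = int(rng.integers(lo, hi + 1))
        klass_planted[genes[gi_loc].gene_id] = class_names[cls_i]
    for gi_loc in designed_set:
        lo, hi = config.width_ranges["designed_bd"]
        widths[genes[gi_loc].gene_id] = int(rng.integers(lo, hi + 1))
        klass_planted[genes[gi_loc].gene_id] = "broad"

    planted_bd = _planted_bd_flags(widths, annotation) if widths else set()

    # --- the KO-affected (reduced) gene set
    if design is not None:
        affected = {genes[int(i)].gene_id for i in designed_c}
    else:
        bd_sorted = sorted(planted_bd)
        k = int(round(config.ko_bd_fraction * len(bd_sorted)))
        affected = (
            set(rng.choice(bd_sorted, k, replace=False)) if k else set()
        )

    # --- peaks
    halfw = config.promoter_halfwidth
    tss = np.array([g.tss for g in genes])
    chrom_arr = np.array([g.chrom for g in genes])
    k4_peaks: list[Interval] = []
    dom_start = np.zeros(n, dtype=np.int64)
    dom_end = np.zeros(n, dtype=np.int64)
    has_dom = np.zeros(n, dtype=bool)
    for i in domain_idx:
        g = genes[int(i)]
        w = widths[g.gene_id]
        s = max(0, g.tss - w // 2)
        dom_start[i], dom_end[i], has_dom[i] = s, s + w, True
        k4_peaks.append(Interval(g.chrom, s, s + w, name=g.gene_id))
    k27_peaks = [
        Interval(genes[int(i)].chrom, max(0, genes[int(i)].tss - 1500),
                 genes[int(i)].tss + 1500, name=genes[int(i)].gene_id)
        for i in np.flatnonzero(states == 2)
    ]
    foxp3_peaks = [
        Interval(genes[i].chrom, max(0, genes[i].tss - 500), genes[i].tss + 500,
                 name=genes[i].gene_id)
        for i in sorted(foxp3_genes)
    ]
    cxxc1_peaks = [
        Interval(genes[i].chrom, max(0, genes[i].tss - 700), genes[i].tss + 300,
                 name=genes[i].gene_id)
        for i in sorted(cxxc1_genes)
    ]
    bg_candidates = _background_positions(annotation, clearance=halfw + 3000)
    if bg_candidates and config.n_background_peaks:
        take = min(config.n_background_peaks, len(bg_candidates))
        chosen = rng.choice(len(bg_candidates), take, replace=False)
        hw = config.background_peak_width // 2
        for idx in sorted(chosen):
            chrom, mid = bg_candidates[idx]
            bg = Interval(chrom, mid - hw, mid + hw, name="background")
            foxp3_peaks.append(bg)
            cxxc1_peaks.append(bg)

    # --- fragment libraries
    frag_len = config.fragment_length
    win_start = np.maximum(0, tss - halfw)
    win_end = tss + halfw
    # the promoter-window component lands inside window AND domain so that
    # peaks cover their fragments; for domain-less genes, inside the window
    comp_start = np.where(has_dom, np.maximum(win_start, dom_start), win_start)
    comp_end = np.where(has_dom, np.minimum(win_end, dom_end), win_end)
    k4_rates = np.array(config.k4_promoter_rates)[states]
    k27_rates = np.array(config.k27_promoter_rates)[states]
    reduced_mask = np.array([g.gene_id in affected for g in genes])
    ko_scale = np.where(reduced_mask, 1.0 - config.ko_reduction, 1.0)

    def k4_library(scale: np.ndarray) -> pd.DataFrame:
        parts = [
            _uniform_fragments(
                rng, chrom_arr, comp_start, comp_end,
                rng.poisson(k4_rates * scale), frag_len,
            )
        ]
        # flank components: domain minus promoter window, each side
        for seg_s, seg_e in (
            (dom_start, np.minimum(dom_end, win_start)),
            (np.maximum(dom_start, win_end), dom_end),
        ):
            seg_len = np.maximum(0, seg_e - seg_s)
            usable = has_dom & (seg_len > frag_len)
            lam = config.k4_flank_rate_per_kb * seg_len / 1000.0 * scale
            counts = np.where(usable, rng.poisson(np.where(usable, lam, 0.0)), 0)
            parts.append(
                _uniform_fragments(rng, chrom_arr, seg_s, seg_e, counts, frag_len)
            )
        return pd.concat(parts, ignore_index=True)

    frags_wt = k4_library(np.ones(n))
    frags_ko = k4_library(ko_scale)
    frags_k27 = _uniform_fragments(
        rng, chrom_arr, win_start, win_end, rng.poisson(k27_rates), frag_len
    )

    # --- expression linked to state
    expr_vals = np.array(config.expression_means)[states] * rng.lognormal(
        0.0, config.expression_sigma, n
    )
    expression = {g.gene_id: float(v) for g, v in zip(genes, expr_vals)}

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "state": [STATE_LABELS[s] for s in states],
            "has_domain": has_dom,
            "width": [widths.get(g.gene_id, 0) for g in genes],
            "breadth_class": [klass_planted.get(g.gene_id, "") for g in genes],
            "planted_bd": [g.gene_id in planted_bd for g in genes],
            "foxp3_bound": [i in foxp3_genes for i in range(n)],
            "cxxc1_bound": [i in cxxc1_genes for i in range(n)],
            "reduced": reduced_mask,
            "expression": expr_vals,
        }
    )
    return ChromatinSim(
        annotation=annotation,
        peaks={
            "foxp3": foxp3_peaks,
            "cxxc1": cxxc1_peaks,
            "k4me3_wt": k4_peaks,
            "k4me3_ko": list(k4_peaks),
            "h3k27me3": k27_peaks,
        },
        fragments={
            "k4me3_wt": frags_wt,
            "k4me3_ko": frags_ko,
            "h3k27me3": frags_k27,
        },
        totals={
            "k4me3_wt": len(frags_wt),
            "k4me3_ko": len(frags_ko),
            "h3k27me3": len(frags_k27),
        },
        truth=truth,
        expression=expression,
        config=config,
    )


@dataclass
class MethylomeSim:
    calls: pd.DataFrame  # Bismark-coverage-like columns
    elements: dict[str, list[Interval]]
    truth: pd.DataFrame  # per-CpG generating class and mean
    class_expected: dict[str, tuple[int, float]]  # expected estimator mean
    config: SimulationConfig


def _sample_positions(
    rng: np.random.Generator, segments: list[Interval], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n positions uniformly by length over a list of segments."""
    lengths = np.array([s.length for s in segments], dtype=np.int64)
    cum = np.cumsum(lengths)
    draws = rng.integers(0, cum[-1], size=n)
    seg_idx = np.searchsorted(cum, draws, side="right")
    offset = draws - np.concatenate([[0], cum[:-1]])[seg_idx]
    chroms = np.array([segments[i].chrom for i in seg_idx])
    pos = np.array([segments[i].start for i in seg_idx]) + offset
    return chroms, pos


def simulate_methylome(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> MethylomeSim:
    """Plant per-element CpG methylation with Beta-Binomial counts.

    Each CpG is generated from a single element class; CGIs and repeats are
    placed in intergenic space and promoter CpGs upstream of the TSS so the
    headline class means stay identifiable. Composite classes (genebody,
    intergenic) are mixtures; their expected estimator means are recorded in
    ``class_expected``.
    """
    rng = np.random.default_rng([config.seed, 37])
    if not annotation.genes:
        raise ValueError("methylome simulation needs a nonempty annotation")
    # sampling segments per generating class
    seg_map: dict[str, list[Interval]] = {k: [] for k in config.meth_class_proportions}
    cgi_ivs: list[Interval] = []
    repeat_ivs: list[Interval] = []
    for g in annotation.genes:
        lay = gene_layout(g)
        up_far, up_near = (2000, 100)
        if g.strand == "+":
            seg_map["promoter"].append(
                Interval(g.chrom, max(0, g.tss - up_far), g.tss - up_near)
            )
        else:
            seg_map["promoter"].append(
                Interval(g.chrom, g.tss + up_near, g.tss + up_far)
            )
        for klass in ("utr5", "exon", "intron", "utr3"):
            seg_map[klass].append(lay[klass])
        if lay["flank"].length > 1:
            seg_map["genebody"].append(lay["flank"])
    gaps = _background_positions(annotation, clearance=6000)
    if len(gaps) < 4:
        raise ValueError("annotation too dense to place CGIs/repeats/intergenic")
    for i, (chrom, mid) in enumerate(gaps):
        which = i % 3
        if which == 0:
            cgi_ivs.append(Interval(chrom, mid - 250, mid + 250))
        elif which == 1:
            repeat_ivs.append(Interval(chrom, mid - 200, mid + 200))
        else:
            seg_map["intergenic"].append(Interval(chrom, mid - 500, mid + 500))
    seg_map["cgi"] = cgi_ivs
    seg_map["repeats"] = repeat_ivs

    counts = _apportion(
        config.meth_n_cpgs, list(config.meth_class_proportions.values())
    )
    chroms_all, pos_all, mu_all, cls_all = [], [], [], []
    for (klass, _), n_k in zip(config.meth_class_proportions.items(), counts):
        if n_k == 0 or not seg_map[klass]:
            continue
        chroms, pos = _sample_positions(rng, seg_map[klass], int(n_k))
        chroms_all.append(chroms)
        pos_all.append(pos)
        mu_all.append(np.full(int(n_k), config.methylation_means[klass]))
        cls_all.extend([klass] * int(n_k))
    chroms = np.concatenate(chroms_all)
    pos = np.concatenate(pos_all)
    mu = np.clip(np.concatenate(mu_all), 1e-9, 1 - 1e-9)

    rho = config.meth_dispersion
    if rho > 0:
        a = mu * (1 - rho) / rho
        b = (1 - mu) * (1 - rho) / rho
        p = rng.beta(a, b)
    else:
        p = mu
    meth = rng.binomial(config.meth_depth, p)
    unmeth = config.meth_depth - meth
    calls = pd.DataFrame(
        {
            "chrom": chroms,
            "start": pos,
            "end": pos + 1,
            "pct": np.round(100.0 * meth / config.meth_depth, 4),
            "meth": meth,
            "unmeth": unmeth,
        }
    ).sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    truth = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "generating_class": cls_all, "mu": mu}
    ).sort_values(["chrom", "pos"], kind="stable", ignore_index=True)

    # the element map handed to the estimator
    from .methylation import build_element_map

    elements = build_element_map(
        annotation,
        promoter_halfwidth=config.promoter_halfwidth,
        utr5=[gene_layout(g)["utr5"] for g in annotation.genes],
        utr3=[gene_layout(g)["utr3"] for g in annotation.genes],
        cgi=cgi_ivs,
        repeats=repeat_ivs,
    )
    # expected value of the unweighted estimator per class: the mean of the
    # planted Beta means over the CpGs that fall inside the class intervals
    frame = truth.rename(columns={"pos": "pos"})
    class_expected: dict[str, tuple[int, float]] = {}
    for klass in ELEMENT_CLASSES:
        mask = _membership(frame, elements[klass])
        n_in = int(mask.sum())
        if n_in:
            class_expected[klass] = (n_in, float(frame.loc[mask, "mu"].mean()))
    return MethylomeSim(
        calls=calls,
        elements=elements,
        truth=truth,
        class_expected=class_expected,
        config=config,
    )


@dataclass
class TcrSim:
    contigs: pd.DataFrame
    clusters: pd.DataFrame
    truth: dict
    config: SimulationConfig


def _unique_cdr3(rng: np.random.Generator, length: int, seen: set[str]) -> str:
    alphabet = np.array(list("ACGT"))
    while True:
        s = "".join(rng.choice(alphabet, size=length))
        if s not in seen:
            seen.add(s)
            return s


def simulate_tcr(config: SimulationConfig) -> TcrSim:
    """Plant a clonal repertoire with per-cluster expansion and sharing.

    Within each cluster ``round(expansion_fraction * size)`` cells belong to
    expanded clones whose sizes follow a shifted geometric distribution
    (>= 2); the rest are singletons. Expanded clones are shared with an
    earlier cluster at ``sharing_rate``.
    """
    rng = np.random.default_rng([config.seed, 53])
    cluster_sizes = _apportion(config.n_cells, config.tcr_cluster_proportions)
    cluster_names = [f"c{i + 1}" for i in range(len(cluster_sizes))]
    seen: set[str] = set()
    clonotypes: dict[str, tuple[str, str]] = {}

    def new_clonotype() -> str:
        tra = _unique_cdr3(rng, config.cdr3_length, seen)
        trb = _unique_cdr3(rng, config.cdr3_length, seen)
        key = f"ct{len(clonotypes):05d}"
        clonotypes[key] = (tra, trb)
        return key

    cell_rows = []  # (cell_id, cluster, clonotype_id)
    expanded_by_cluster: dict[str, list[str]] = {}
    planted_fraction: dict[str, float] = {}
    n_shared_planted = 0
    cell_i = 0
    for cname, size in zip(cluster_names, cluster_sizes):
        size = int(size)
        n_exp = int(round(config.expansion_fraction * size))
        if n_exp == 1:
            n_exp = 0
        clone_sizes: list[int] = []
        remaining = n_exp
        while remaining >= 2:
            s = 1 + int(rng.geometric(config.clone_geometric_p))
            s = min(s, remaining)
            if remaining - s == 1:
                s += 1
            clone_sizes.append(s)
            remaining -= s
        planted_fraction[cname] = sum(clone_sizes) / size if size else 0.0
        expanded_by_cluster[cname] = []
        prior_pool = [
            key for other, keys in expanded_by_cluster.items()
            if other != cname for key in keys
        ]
        for s in clone_sizes:
            if prior_pool and rng.random() < config.sharing_rate:
                key = prior_pool[int(rng.integers(len(prior_pool)))]
                n_shared_planted += 1
            else:
                key = new_clonotype()
            expanded_by_cluster[cname].append(key)
            for _ in range(s):
                cell_rows.append((f"cell{cell_i:05d}", cname, key))
                cell_i += 1
        for _ in range(size - sum(clone_sizes)):
            cell_rows.append((f"cell{cell_i:05d}", cname, new_clonotype()))
            cell_i += 1

    contig_rows = []
    umi_lo, umi_hi = config.umi_range
    for cell_id, cname, key in cell_rows:
        tra, trb = clonotypes[key]
        umi_a = int(rng.integers(umi_lo, umi_hi + 1))
        umi_b = int(rng.integers(umi_lo, umi_hi + 1))
        contig_rows.append((cell_id, "TRA", tra, umi_a))
        contig_rows.append((cell_id, "TRB", trb, umi_b))
        if rng.random() < config.decoy_chain_fraction and umi_a > 1:
            decoy = _unique_cdr3(rng, config.cdr3_length + 3, seen)
            contig_rows.append(
                (cell_id, "TRA", decoy, int(rng.integers(1, umi_a)))
            )
    contigs = pd.DataFrame(
        contig_rows, columns=["cell_id", "locus", "cdr3_nt", "umi_count"]
    )
    clusters = pd.DataFrame(
        [(cid, cname) for cid, cname, _ in cell_rows],
        columns=["cell_id", "cluster"],
    )
    truth = {
        "planted_fraction": planted_fraction,
        "n_shared_planted": n_shared_planted,
        "cell_clonotype": {cid: key for cid, _, key in cell_rows},
        "clonotype_chains": clonotypes,
    }
    return TcrSim(contigs=contigs, clusters=clusters, truth=truth, config=config)
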