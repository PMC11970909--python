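"""Gene models, genome annotation, and peak-to-feature classification.

The transcription start site (TSS) is strand-aware: ``tx_start`` for ``+``
genes and ``tx_end`` for ``-`` genes. Promoter windows are ``TSS +/-
halfwidth`` (default 2 kb), clipped at chromosome boundaries when sizes are
known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from intervaltree import IntervalTree

from .intervals import Interval, overlap_length

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "classify_genomic_region",
    "classify_genomic_regions",
    "assign_peaks_to_genes",
]

RegionCategory = Literal["promoter", "exon", "intron", "intergenic"]
AssignMode = Literal["promoter_only", "gene_or_promoter"]


@dataclass(slots=True)
class GeneModel:
    """A strand-aware gene record with exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= tx_start < tx_end, "
                f"got [{self.tx_start}, {self.tx_end})"
            )
        prev_end = self.tx_start
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < prev_end or ex.end > self.tx_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, non-overlapping "
                    f"and contained in the transcript span"
                )
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter_window(
        self, halfwidth: int = 2000, chrom_length: int | None = None
    ) -> Interval:
        start = max(0, self.tss - halfwidth)
        end = self.tss + halfwidth
        if chrom_length is not None:
            end = min(end, chrom_length)
        return Interval(self.chrom, start, end, name=self.gene_id)

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.tx_start, self.tx_end, name=self.gene_id)


@dataclass
class GenomeAnnotation:
    """A set of gene models plus chromosome lengths."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.tx_end > size:
                raise ValueError(
                    f"gene {g.gene_id} exceeds chromosome {g.chrom} length {size}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def chrom_length(self, chrom: str) -> int | None:
        return self.chrom_sizes.get(chrom)


def _feature_trees(
    annotation: GenomeAnnotation, promoter_halfwidth: int
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree], dict[str, IntervalTree]]:
    """Build promoter / exon / gene-body interval trees keyed by chromosome."""
    promoters: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for gi, g in enumerate(annotation.genes):
        win = g.promoter_window(promoter_halfwidth, annotation.chrom_length(g.chrom))
        promoters.setdefault(g.chrom, IntervalTree()).addi(win.start, win.end, gi)
        bodies.setdefault(g.chrom, IntervalTree()).addi(g.tx_start, g.tx_end, gi)
        for ex in g.exons:
            exons.setdefault(g.chrom, IntervalTree()).addi(ex.start, ex.end, gi)
    return promoters, exons, bodies


def classify_genomic_regions(
    peaks: Sequence[Interval],
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
) -> list[RegionCategory]:
    """Classify peaks as promoter / exon / intron / intergenic.

    Precedence is promoter > exon > intron > intergenic with any-overlap
    membership: a peak touching any promoter window is "promoter" no matter
    what else it overlaps; otherwise any exonic overlap wins over intronic,
    and a peak inside a gene with no exon overlap is "intron".
    """
    if not annotation.genes:
        raise ValueError("annotation must contain at least one gene")
    promoters, exons, bodies = _feature_trees(annotation, promoter_halfwidth)
    out: list[RegionCategory] = []
    for p in peaks:
        if promoters.get(p.chrom) and promoters[p.chrom].overlap(p.start, p.end):
            out.append("promoter")
        elif exons.get(p.chrom) and exons[p.chrom].overlap(p.start, p.end):
            out.append("exon")
        elif bodies.get(p.chrom) and bodies[p.chrom].overlap(p.start, p.end):
            out.append("intron")
        else:
            out.append("intergenic")
    return out


def classify_genomic_region(
    peak: Interval,
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
) -> RegionCategory:
    """Single-peak convenience wrapper around :func:`classify_genomic_regions`."""
    return classify_genomic_regions([peak], annotation, promoter_halfwidth)[0]


def assign_peaks_to_genes(
    peaks: Sequence[Interval],
    annotation: GenomeAnnotation,
    mode: AssignMode = "gene_or_promoter",
    promoter_halfwidth: int = 2000,
    min_bp: int = 1,
) -> dict[str, list[int]]:
    """Map each gene to the indices of peaks overlapping it.

    ``promoter_only`` assigns a peak when it overlaps the gene's promoter
    window; ``gene_or_promoter`` additionally accepts overlap with the
    transcript span. A peak may be assigned to multiple genes; genes with no
    peaks map to empty lists.
    """
    if mode not in ("promoter_only", "gene_or_promoter"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(annotation.genes):
        win = g.promoter_window(promoter_halfwidth, annotation.chrom_length(g.chrom))
        tree = trees.setdefault(g.chrom, IntervalTree())
        tree.addi(win.start, win.end, gi)
        if mode == "gene_or_promoter":
            tree.addi(g.tx_start, g.tx_end, gi)
    assigned: dict[str, set[int]] = {g.gene_id: set() for g in annotation.genes}
    for pi, p in enumerate(peaks):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            if min(p.end, hit.end) - max(p.start, hit.begin) >= min_bp:
                assigned[annotation.genes[hit.data].gene_id].add(pi)
    return {gid: sorted(pis) for gid, pis in assigned.items()}
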