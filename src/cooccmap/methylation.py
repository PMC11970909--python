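"""Feature-level WGBS summaries: mean CpG methylation per genome-element class.

Classes (promoter, 5'-UTR, exon, intron, 3'-UTR, genebody, intergenic, CGI,
repeats) are non-exclusive except genebody/intergenic, which partition the
genome: a promoter CpG inside a CGI contributes to both classes. Methylation
levels are recomputed from counts, never trusted from a percentage column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation
from .intervals import Interval, merge_intervals

__all__ = [
    "ELEMENT_CLASSES",
    "CpGCall",
    "read_cpg_calls",
    "element_mean_methylation",
    "build_element_map",
]

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = (
    "promoter",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "genebody",
    "intergenic",
    "cgi",
    "repeats",
)


@dataclass(slots=True)
class CpGCall:
    """A per-CpG methylation observation."""

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.total_count < self.meth_count:
            raise ValueError("need 0 <= meth_count <= total_count")
        if self.total_count < 1:
            raise ValueError("retained calls need total_count >= 1")

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


def read_cpg_calls(path: str | Path) -> list[CpGCall]:
    """Read a Bismark-coverage-like TSV: chrom, start, end, level%, meth,
    unmeth.

    Zero-coverage rows are dropped (count logged); the percentage column is
    recomputed from counts and discrepancies are logged, with counts winning.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
        comment="#",
    )
    if (frame[["meth", "unmeth"]] < 0).any().any():
        bad = frame.index[(frame["meth"] < 0) | (frame["unmeth"] < 0)][0]
        raise ValueError(f"line {bad + 1}: negative methylation counts")
    total = frame["meth"] + frame["unmeth"]
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.info("read_cpg_calls: dropped %d zero-coverage CpGs", n_zero)
    keep = frame[total > 0].copy()
    keep_total = keep["meth"] + keep["unmeth"]
    recomputed = 100.0 * keep["meth"] / keep_total
    n_bad_pct = int((np.abs(recomputed - keep["pct"]) > 0.51).sum())
    if n_bad_pct:
        logger.warning(
            "read_cpg_calls: %d rows have a percentage column inconsistent "
            "with counts; counts win",
            n_bad_pct,
        )
    return [
        CpGCall(chrom=r.chrom, pos=int(r.start), meth_count=int(r.meth),
                total_count=int(r.meth + r.unmeth))
        for r in keep.itertuples(index=False)
    ]


def _calls_to_arrays(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": np.asarray([c.pos for c in calls], dtype=np.int64),
            "meth": np.asarray([c.meth_count for c in calls], dtype=np.int64),
            "total": np.asarray([c.total_count for c in calls], dtype=np.int64),
        }
    )


def _membership(
    frame: pd.DataFrame, intervals: Sequence[Interval]
) -> np.ndarray:
    """Boolean mask: which CpGs fall inside the (merged) class intervals."""
    mask = np.zeros(len(frame), dtype=bool)
    if not intervals:
        return mask
    merged = merge_intervals(intervals)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in merged}:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    pos_all = frame["pos"].to_numpy()
    for chrom, (starts, ends) in by_chrom.items():
        rows = np.flatnonzero((frame["chrom"] == chrom).to_numpy())
        if rows.size == 0:
            continue
        pos = pos_all[rows]
        # merged intervals are disjoint and sorted: CpG is inside iff the
        # last interval starting at or before it also ends beyond it
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        mask[rows[inside]] = True
    return mask


def element_mean_methylation(
    calls,
    elements: Mapping[str, Sequence[Interval]],
    min_coverage: int = 1,
    weighting: str = "cpg_unweighted",
) -> pd.DataFrame:
    """Mean methylation per element class.

    ``cpg_unweighted`` averages per-CpG levels; ``coverage_weighted`` pools
    counts (sum meth / sum total). Classes with zero qualifying CpGs are
    omitted from the table, never reported as 0.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if weighting not in ("cpg_unweighted", "coverage_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    frame = _calls_to_arrays(calls)
    frame = frame[frame["total"] >= min_coverage]
    rows = []
    for klass, intervals in elements.items():
        mask = _membership(frame, intervals)
        n = int(mask.sum())
        if n == 0:
            continue
        meth = frame.loc[mask, "meth"].to_numpy(dtype=float)
        total = frame.loc[mask, "total"].to_numpy(dtype=float)
        if weighting == "cpg_unweighted":
            mean = float(np.mean(meth / total))
        else:
            mean = float(meth.sum() / total.sum())
        rows.append({"class": klass, "n_cpgs": n, "mean_level": mean})
    return pd.DataFrame(rows, columns=["class", "n_cpgs", "mean_level"])


def build_element_map(
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
    utr5: Sequence[Interval] | None = None,
    utr3: Sequence[Interval] | None = None,
    cgi: Sequence[Interval] | None = None,
    repeats: Sequence[Interval] | None = None,
    intron: Sequence[Interval] | None = None,
    exon: Sequence[Interval] | None = None,
) -> dict[str, list[Interval]]:
    """Derive an element class map from a gene annotation.

    Promoter, genebody and intergenic come from the annotation (intergenic is
    the genebody complement over chromosomes with known sizes, so the two are
    complementary by construction). Exon defaults to the annotated exons and
    intron to the within-gene remainder; UTRs, CGIs and repeats are direct
    interval inputs since the gene model carries no CDS information.
    """
    promoters = [
        g.promoter_window(promoter_halfwidth, annotation.chrom_length(g.chrom))
        for g in annotation.genes
    ]
    bodies = [g.span for g in annotation.genes]
    if exon is None:
        exon = [ex for g in annotation.genes for ex in g.exons]
    if intron is None:
        intron = []
        for g in annotation.genes:
            cursor = g.tx_start
            for ex in g.exons:
                if ex.start > cursor:
                    intron.append(Interval(g.chrom, cursor, ex.start))
                cursor = ex.end
            if g.tx_end > cursor:
                intron.append(Interval(g.chrom, cursor, g.tx_end))
    intergenic: list[Interval] = []
    merged_bodies = merge_intervals(bodies) if bodies else []
    for chrom, size in annotation.chrom_sizes.items():
        cursor = 0
        for blk in [b for b in merged_bodies if b.chrom == chrom]:
            if blk.start > cursor:
                intergenic.append(Interval(chrom, cursor, blk.start))
            cursor = blk.end
        if cursor < size:
            intergenic.append(Interval(chrom, cursor, size))
    return {
        "promoter": promoters,
        "utr5": list(utr5 or []),
        "exon": list(exon),
        "intron": list(intron),
        "utr3": list(utr3 or []),
        "genebody": bodies,
        "intergenic": intergenic,
        "cgi": list(cgi or []),
        "repeats": list(repeats or []),
    }
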