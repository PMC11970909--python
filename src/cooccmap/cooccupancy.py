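"""Gene-level binding sets, Venn-region counts and co-occupancy fractions.

A gene is FOXP3- or CXXC1-bound when a peak overlaps its transcript span or
promoter window (``gene_or_promoter``); H3K4me3-enriched when a peak
overlaps the promoter window (``promoter_only``). The BD-reduced flag comes
from the breadth analysis. Percentages in report strings are rounded
half-up to integers; full-precision fractions are kept in tables.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Set

import pandas as pd

from .genome import GenomeAnnotation, assign_peaks_to_genes
from .intervals import Interval, intersect_sets

__all__ = [
    "BINDING_FLAGS",
    "gene_binding_sets",
    "venn_counts",
    "cooccupancy_fraction",
    "peak_level_overlap",
]

BINDING_FLAGS = ("foxp3_bound", "cxxc1_bound", "k4me3_enriched", "bd_reduced")

VENN_REGIONS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc", "outside")


def gene_binding_sets(
    foxp3_peaks: Sequence[Interval],
    cxxc1_peaks: Sequence[Interval],
    k4me3_peaks: Sequence[Interval],
    annotation: GenomeAnnotation,
    bd_reduced: Set[str] | None = None,
    tf_mode: str = "gene_or_promoter",
    k4_mode: str = "promoter_only",
    promoter_halfwidth: int = 2000,
) -> pd.DataFrame:
    """Boolean membership flags for every annotated gene.

    Returns a DataFrame indexed by gene_id with columns ``foxp3_bound``,
    ``cxxc1_bound``, ``k4me3_enriched`` and ``bd_reduced``.
    """

    def bound(peaks: Sequence[Interval], mode: str) -> set[str]:
        assigned = assign_peaks_to_genes(
            peaks, annotation, mode=mode, promoter_halfwidth=promoter_halfwidth
        )
        return {gid for gid, pis in assigned.items() if pis}

    foxp3 = bound(foxp3_peaks, tf_mode)
    cxxc1 = bound(cxxc1_peaks, tf_mode)
    k4 = bound(k4me3_peaks, k4_mode)
    reduced = set(bd_reduced or ())
    gene_ids = annotation.gene_ids
    return pd.DataFrame(
        {
            "foxp3_bound": [g in foxp3 for g in gene_ids],
            "cxxc1_bound": [g in cxxc1 for g in gene_ids],
            "k4me3_enriched": [g in k4 for g in gene_ids],
            "bd_reduced": [g in reduced for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def venn_counts(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    universe: Iterable[str],
) -> dict[str, int]:
    """Exact cardinalities of the 7 regions of a 3-set Venn plus the outside.

    Region keys: ``a_only``, ``b_only``, ``c_only``, ``ab`` (A and B only),
    ``ac``, ``bc``, ``abc``, ``outside``. Every set must be contained in the
    universe.
    """
    a, b, c, u = set(set_a), set(set_b), set(set_c), set(universe)
    for name, s in (("A", a), ("B", b), ("C", c)):
        extra = s - u
        if extra:
            raise ValueError(
                f"set {name} contains {len(extra)} element(s) outside the universe"
            )
    abc = a & b & c
    counts = {
        "abc": len(abc),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
    }
    counts["outside"] = len(u) - sum(counts.values())
    return counts


def _round_half_up_pct(fraction: float) -> int:
    return int(math.floor(fraction * 100 + 0.5))


def cooccupancy_fraction(
    sets: pd.DataFrame,
    numerator_flags: Sequence[str],
    denominator_flags: Sequence[str],
) -> tuple[int, int, float, str]:
    """Fraction of genes with all denominator flags that also carry the
    numerator flags.

    The numerator conjunction is applied on top of the denominator, so the
    numerator set is a subset of the denominator by construction. Returns
    ``(count_num, count_den, fraction, percent_string)`` and raises when the
    denominator is empty.
    """
    for flag in list(numerator_flags) + list(denominator_flags):
        if flag not in sets.columns:
            raise ValueError(f"unknown binding flag {flag!r}")
    den_mask = sets[list(denominator_flags)].all(axis=1)
    count_den = int(den_mask.sum())
    if count_den == 0:
        raise ValueError("denominator selects no genes")
    num_mask = den_mask & sets[list(numerator_flags)].all(axis=1)
    count_num = int(num_mask.sum())
    fraction = count_num / count_den
    return count_num, count_den, fraction, f"{_round_half_up_pct(fraction)}%"


def peak_level_overlap(
    peaks_a: Sequence[Interval],
    peaks_b: Sequence[Interval],
    min_bp: int = 1,
) -> float:
    """Fraction of peaks in A overlapping at least one peak in B.

    Each A peak is counted once regardless of partner multiplicity; the
    measure is asymmetric in general.
    """
    if not peaks_a:
        raise ValueError("peaks_a must be nonempty")
    pairs = intersect_sets(peaks_a, peaks_b, min_bp=min_bp)
    hit = {i for i, _ in pairs}
    return len(hit) / len(peaks_a)
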