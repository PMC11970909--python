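"""Promoter windows, fragment counting, and RPKM normalization.

Promoters are TSS +/- 2 kb by default. A fragment counts toward a window
when it overlaps by at least ``min_overlap`` bp (default 1, matching
coverage-command semantics); a fragment may count toward several windows.
RPKM uses the total mapped fragments of the library as the denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation
from .intervals import Interval, count_overlaps

__all__ = [
    "PromoterWindow",
    "SignalMatrix",
    "make_promoters",
    "count_fragments",
    "rpkm",
    "quantify_promoters",
]


@dataclass(slots=True)
class PromoterWindow:
    gene_id: str
    window: Interval


def make_promoters(
    annotation: GenomeAnnotation, halfwidth: int = 2000
) -> list[PromoterWindow]:
    """One strand-aware promoter window per gene, clipped at chromosome edges.

    Raises if a gene sits on a chromosome absent from ``chrom_sizes`` when
    sizes are provided (silent extension past a boundary would corrupt RPKM
    lengths).
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    windows = []
    for g in annotation.genes:
        if annotation.chrom_sizes and g.chrom not in annotation.chrom_sizes:
            raise ValueError(
                f"gene {g.gene_id} lies on unknown chromosome {g.chrom!r}"
            )
        win = g.promoter_window(halfwidth, annotation.chrom_length(g.chrom))
        windows.append(PromoterWindow(gene_id=g.gene_id, window=win))
    return windows


def count_fragments(
    fragments,
    windows: Sequence[PromoterWindow],
    min_overlap: int = 1,
) -> np.ndarray:
    """Fragments overlapping each promoter window by >= ``min_overlap`` bp.

    ``fragments`` is a list of :class:`Interval` or a chrom/start/end
    DataFrame.
    """
    if not windows:
        raise ValueError("windows must be nonempty")
    return count_overlaps(fragments, [w.window for w in windows], min_overlap)


def rpkm(count, window_length, total_fragments):
    """Reads per kilobase of window per million mapped fragments.

    Vectorized over ``count``/``window_length``.
    """
    total = float(total_fragments)
    if total <= 0:
        raise ValueError("total_fragments must be > 0")
    length = np.asarray(window_length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("window_length must be > 0")
    value = np.asarray(count, dtype=float) / ((length / 1e3) * (total / 1e6))
    return float(value) if np.isscalar(count) else value


@dataclass
class SignalMatrix:
    """Genes x samples RPKM matrix with per-sample library totals."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    totals: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with gene/sample ids")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("RPKM values must be finite and >= 0")
        for s in self.sample_ids:
            if self.totals.get(s, 0) <= 0:
                raise ValueError(f"sample {s}: library total must be > 0")

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with a ``<path>.totals.json`` sidecar."""
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")
        with open(f"{path}.totals.json", "w") as fh:
            json.dump(self.totals, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        with open(f"{path}.totals.json") as fh:
            totals = json.load(fh)
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=list(frame.columns),
            values=frame.to_numpy(),
            totals={k: int(v) for k, v in totals.items()},
        )


def quantify_promoters(
    annotation: GenomeAnnotation,
    sample_fragments: Mapping[str, object],
    totals: Mapping[str, int] | None = None,
    halfwidth: int = 2000,
    min_overlap: int = 1,
) -> SignalMatrix:
    """Count fragments per promoter for each sample and normalize to RPKM.

    ``sample_fragments`` maps sample id to a fragment list/DataFrame. When
    ``totals`` is omitted the library size defaults to the number of supplied
    fragments.
    """
    windows = make_promoters(annotation, halfwidth)
    lengths = np.array([w.window.length for w in windows], dtype=float)
    sample_ids = list(sample_fragments)
    values = np.zeros((len(windows), len(sample_ids)))
    lib_totals: dict[str, int] = {}
    for j, sid in enumerate(sample_ids):
        frags = sample_fragments[sid]
        total = int(totals[sid]) if totals is not None else len(frags)
        counts = count_fragments(frags, windows, min_overlap)
        values[:, j] = rpkm(counts, lengths, total)
        lib_totals[sid] = total
    return SignalMatrix(
        gene_ids=[w.gene_id for w in windows],
        sample_ids=sample_ids,
        values=values,
        totals=lib_totals,
    )
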