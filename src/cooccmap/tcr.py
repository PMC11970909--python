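"""Single-cell TCR repertoire: clonotype calling, expansion and sharing.

A cell's clonotype is the pair of CDR3 nucleotide sequences of its
highest-UMI TRA and TRB chains, keyed ``"<TRA>_<TRB>"`` with ``NA`` for a
missing locus. A clonotype is expanded when it is detected in at least two
cells. Cross-cluster sharing uses the overlap coefficient
``|Sx & Sy| / min(|Sx|, |Sy|)`` by default (Jaccard available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChainRecord",
    "CellClonotype",
    "read_contigs",
    "read_clusters",
    "call_clonotypes",
    "expanded_clonotypes",
    "clonal_overlap",
    "expansion_density",
]

logger = logging.getLogger(__name__)

_LOCI = {"TRA", "TRB"}
_NT = set("ACGT")


@dataclass(slots=True)
class ChainRecord:
    cell_id: str
    locus: str
    cdr3_nt: str
    umi_count: int

    def __post_init__(self) -> None:
        if self.locus not in _LOCI:
            raise ValueError(f"locus must be TRA or TRB, got {self.locus!r}")
        if not self.cdr3_nt or set(self.cdr3_nt) - _NT:
            raise ValueError(f"invalid CDR3 nucleotide string {self.cdr3_nt!r}")
        if self.umi_count < 1:
            raise ValueError("umi_count must be >= 1")


@dataclass(slots=True)
class CellClonotype:
    cell_id: str
    clonotype_key: str
    cluster_label: str


def read_contigs(path: str | Path) -> list[ChainRecord]:
    """Read a contig table (CSV or TSV by extension) with columns cell_id,
    locus, cdr3_nt, umi_count."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, dtype={"cell_id": str})
    return [
        ChainRecord(
            cell_id=r.cell_id,
            locus=r.locus,
            cdr3_nt=r.cdr3_nt,
            umi_count=int(r.umi_count),
        )
        for r in frame.itertuples(index=False)
    ]


def read_clusters(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def _best_chain(chains: list[ChainRecord]) -> str | None:
    """Highest-UMI CDR3 for one locus; ties take the lexicographically
    smallest sequence."""
    if not chains:
        return None
    return min(chains, key=lambda c: (-c.umi_count, c.cdr3_nt)).cdr3_nt


def call_clonotypes(
    chains: Sequence[ChainRecord],
    clusters: Mapping[str, str],
) -> list[CellClonotype]:
    """One clonotype per cell from its top-expression TRA and TRB chains.

    Chains whose cell is missing from ``clusters`` are dropped (count
    logged), as are cells lacking both loci. Output is sorted by cell_id.
    """
    per_cell: dict[str, dict[str, list[ChainRecord]]] = {}
    n_dropped = 0
    for ch in chains:
        if ch.cell_id not in clusters:
            n_dropped += 1
            continue
        per_cell.setdefault(ch.cell_id, {"TRA": [], "TRB": []})[ch.locus].append(ch)
    if n_dropped:
        logger.info("call_clonotypes: dropped %d chains with unknown cells", n_dropped)
    out = []
    for cell_id in sorted(per_cell):
        tra = _best_chain(per_cell[cell_id]["TRA"])
        trb = _best_chain(per_cell[cell_id]["TRB"])
        if tra is None and trb is None:
            continue
        out.append(
            CellClonotype(
                cell_id=cell_id,
                clonotype_key=f"{tra or 'NA'}_{trb or 'NA'}",
                cluster_label=clusters[cell_id],
            )
        )
    return out


def expanded_clonotypes(cells: Sequence[CellClonotype]) -> set[str]:
    """Clonotype keys detected in at least two cells."""
    counts = pd.Series([c.clonotype_key for c in cells]).value_counts()
    return set(counts.index[counts >= 2])


def clonal_overlap(
    cells: Sequence[CellClonotype],
    expanded_only: bool = True,
    metric: str = "overlap",
) -> pd.DataFrame:
    """Symmetric cluster-by-cluster clonotype sharing matrix.

    ``overlap`` computes ``|Sx & Sy| / min(|Sx|, |Sy|)``; ``jaccard`` uses
    the union denominator. The diagonal is 1 for clusters with a nonempty
    clonotype set; comparisons involving an empty set yield 0 with a logged
    warning.
    """
    if metric not in ("overlap", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    cluster_names = sorted({c.cluster_label for c in cells})
    if len(cluster_names) < 2:
        raise ValueError("clonal_overlap needs at least two clusters")
    keep = expanded_clonotypes(cells) if expanded_only else None
    sets: dict[str, set[str]] = {name: set() for name in cluster_names}
    for c in cells:
        if keep is None or c.clonotype_key in keep:
            sets[c.cluster_label].add(c.clonotype_key)
    n = len(cluster_names)
    mat = np.zeros((n, n))
    for i, x in enumerate(cluster_names):
        for j, y in enumerate(cluster_names):
            sx, sy = sets[x], sets[y]
            if not sx or not sy:
                mat[i, j] = 0.0
                if i <= j:
                    logger.warning(
                        "clonal_overlap: empty clonotype set for %s/%s", x, y
                    )
                continue
            inter = len(sx & sy)
            den = min(len(sx), len(sy)) if metric == "overlap" else len(sx | sy)
            mat[i, j] = inter / den
    return pd.DataFrame(mat, index=cluster_names, columns=cluster_names)


def expansion_density(cells: Sequence[CellClonotype]) -> pd.DataFrame:
    """Per-cluster cell count, expanded-cell fraction, and clonotype richness.

    Expansion is assessed over the whole dataset (a clonotype seen once in
    each of two clusters still counts as expanded).
    """
    expanded = expanded_clonotypes(cells)
    rows = []
    by_cluster: dict[str, list[CellClonotype]] = {}
    for c in cells:
        by_cluster.setdefault(c.cluster_label, []).append(c)
    for name in sorted(by_cluster):
        members = by_cluster[name]
        n = len(members)
        n_exp = sum(1 for c in members if c.clonotype_key in expanded)
        rows.append(
            {
                "cluster": name,
                "n_cells": n,
                "expanded_fraction": n_exp / n,
                "richness": len({c.clonotype_key for c in members}),
            }
        )
    return pd.DataFrame(rows)
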