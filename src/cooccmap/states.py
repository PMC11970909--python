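"""Promoter chromatin-state clustering.

Promoters are partitioned into k states (default 4) by k-means on
log2(RPKM+1)-transformed H3K4me3 and H3K27me3 signal. With k=4 the states
receive semantic labels from the centroid ranking: the two clusters with the
highest mean H3K4me3 become ``K4_high_A`` (higher) and ``K4_high_B``; of the
remaining two, the one with higher H3K27me3 becomes ``K27_high`` and the
last ``both_low``. Labels depend on centroid ranking only, never on the raw
cluster index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .quantify import SignalMatrix

__all__ = [
    "STATE_LABELS",
    "PromoterStateModel",
    "PromoterStateResults",
    "cluster_promoters",
    "label_states",
    "state_expression_summary",
]

logger = logging.getLogger(__name__)

STATE_LABELS = ("K4_high_A", "K4_high_B", "K27_high", "both_low")


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(values + 1.0)
    if transform == "none":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown transform {transform!r}")


def label_states(centroids: np.ndarray) -> list[str]:
    """Semantic labels for k=4 centroids given as (K4, K27) rows.

    Ties in centroid means are broken by row index (lower index wins the
    higher-signal label).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (4, 2):
        raise ValueError("semantic labels are defined for k=4 with 2 marks")
    order_k4 = sorted(range(4), key=lambda i: (-centroids[i, 0], i))
    labels = [""] * 4
    labels[order_k4[0]] = "K4_high_A"
    labels[order_k4[1]] = "K4_high_B"
    rest = sorted(order_k4[2:], key=lambda i: (-centroids[i, 1], i))
    labels[rest[0]] = "K27_high"
    labels[rest[1]] = "both_low"
    return labels


@dataclass
class PromoterStateModel:
    """k-means state model over two histone-mark signal columns.

    Parameters
    ----------
    k : int
        Number of chromatin states (default 4).
    seed : int
        Base seed; restart ``i`` uses ``seed + i``, and the restart with the
        lowest within-cluster sum of squares wins, so the fit is
        deterministic given ``(seed, n_init)``.
    n_init : int
        Number of independent Lloyd's-algorithm restarts.
    transform : {"log2p1", "none"}
        Signal transform applied before clustering.
    """

    k: int = 4
    seed: int = 0
    n_init: int = 10
    transform: str = "log2p1"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")

    def fit(
        self,
        matrix: SignalMatrix,
        k4_col: str = "H3K4me3",
        k27_col: str = "H3K27me3",
    ) -> "PromoterStateResults":
        for col in (k4_col, k27_col):
            if col not in matrix.sample_ids:
                raise ValueError(f"matrix lacks required column {col!r}")
        X = _transform(
            np.column_stack([matrix.column(k4_col), matrix.column(k27_col)]),
            self.transform,
        )
        n_distinct = np.unique(X, axis=0).shape[0]
        if n_distinct < self.k:
            raise ValueError(
                f"only {n_distinct} distinct promoter signal points; "
                f"choose k <= {n_distinct}"
            )
        best = None
        inertias = []
        for i in range(self.n_init):
            km = KMeans(
                n_clusters=self.k,
                n_init=1,
                random_state=self.seed + i,
                algorithm="lloyd",
            ).fit(X)
            inertias.append(km.inertia_)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        # reindex clusters by descending K4 centroid so cluster 1 is the
        # strongest H3K4me3 state regardless of the k-means internal order
        order = sorted(
            range(self.k), key=lambda i: (-best.cluster_centers_[i, 0], i)
        )
        remap = {old: new for new, old in enumerate(order)}
        centroids = best.cluster_centers_[order]
        clusters = np.array([remap[c] for c in best.labels_], dtype=int)
        labels = (
            label_states(centroids)
            if self.k == 4
            else [f"state_{i + 1}" for i in range(self.k)]
        )
        return PromoterStateResults(
            model=self,
            gene_ids=list(matrix.gene_ids),
            clusters=clusters,
            centroids=centroids,
            cluster_labels=labels,
            inertia=float(best.inertia_),
            restart_inertias=[float(v) for v in inertias],
        )


@dataclass
class PromoterStateResults:
    """Fitted state assignment: clusters, centroids and semantic labels."""

    model: PromoterStateModel
    gene_ids: list[str]
    clusters: np.ndarray  # 0-based cluster index, ordered by descending K4
    centroids: np.ndarray  # k x 2 in transformed space, same order
    cluster_labels: list[str]
    inertia: float
    restart_inertias: list[float] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        """Per-gene semantic state label."""
        return [self.cluster_labels[c] for c in self.clusters]

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "cluster": self.clusters + 1,
                "label": self.labels,
            }
        )

    def centroid_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": np.arange(self.model.k) + 1,
                "label": self.cluster_labels,
                "k4_centroid": self.centroids[:, 0],
                "k27_centroid": self.centroids[:, 1],
            }
        )

    def summary(self) -> pd.DataFrame:
        """Cluster sizes and centroids, one row per state."""
        sizes = np.bincount(self.clusters, minlength=self.model.k)
        table = self.centroid_table()
        table.insert(2, "n_genes", sizes)
        return table


def cluster_promoters(
    matrix: SignalMatrix,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    transform: str = "log2p1",
    k4_col: str = "H3K4me3",
    k27_col: str = "H3K27me3",
) -> PromoterStateResults:
    """Functional wrapper: fit a :class:`PromoterStateModel` on a matrix."""
    model = PromoterStateModel(k=k, seed=seed, n_init=n_init, transform=transform)
    return model.fit(matrix, k4_col=k4_col, k27_col=k27_col)


def state_expression_summary(
    results: PromoterStateResults,
    expression: dict[str, float],
) -> pd.DataFrame:
    """Mean/median expression per chromatin state.

    Genes without an expression value are skipped (count logged), never
    imputed. Raises when no clustered gene has expression.
    """
    rows = []
    labels = results.labels
    n_missing = 0
    per_label: dict[str, list[float]] = {}
    for gid, lab in zip(results.gene_ids, labels):
        if gid in expression:
            per_label.setdefault(lab, []).append(float(expression[gid]))
        else:
            n_missing += 1
    if not per_label:
        raise ValueError("expression table shares no genes with the clustering")
    if n_missing:
        logger.info("state_expression_summary: %d genes lack expression", n_missing)
        if n_missing > len(results.gene_ids) / 2:
            logger.warning(
                "expression covers fewer than half of the clustered genes"
            )
    for lab in results.cluster_labels:
        if lab not in per_label:
            continue
        vals = np.asarray(per_label[lab])
        rows.append(
            {
                "label": lab,
                "n_genes": len(vals),
                "mean_expression": float(vals.mean()),
                "median_expression": float(np.median(vals)),
            }
        )
    return pd.DataFrame(rows)
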