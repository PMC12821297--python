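"""Dataset-level correlation structure: Spearman matrix, dendrogram cluster
calling with a positive-dominance rule, and an optional 2-D embedding."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class DatasetCluster:
    """A called group of concordant datasets."""

    label: str
    members: list[str]
    merge_height: float
    positive_fraction: float


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of dataset columns (ties: mean rank).

    A constant column has undefined correlation; its off-diagonal cells are
    recorded as missing with a warning.
    """
    if matrix.shape[1] < 2:
        raise PipelineError("spearman_matrix requires at least 2 datasets")
    ranks = matrix.rank(axis=0, method="average")
    constant = matrix.nunique(dropna=True) <= 1
    if constant.any():
        logger.warning(
            "spearman_matrix: constant column(s) %s have undefined correlation",
            list(matrix.columns[constant]),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pandas warns on zero-variance columns
        corr = ranks.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _auto_cutoff(merge_heights: np.ndarray) -> float:
    """Cut at the midpoint of the largest gap between consecutive merges."""
    heights = np.sort(merge_heights)
    if len(heights) < 2:
        return float(heights[-1]) if len(heights) else 0.0
    gaps = np.diff(heights)
    i = int(np.argmax(gaps))
    return float((heights[i] + heights[i + 1]) / 2.0)


def call_clusters(
    corr: pd.DataFrame,
    linkage: str = "average",
    height_cutoff: float | None = None,
    min_size: int = 3,
    dominance: float = 0.9,
) -> list[DatasetCluster]:
    """Agglomerate on d = 1 - rho, cut the dendrogram, keep groups of
    ``min_size``+ whose fraction of positive within-pair correlations meets
    the ``dominance`` threshold.

    ``height_cutoff=None`` picks the cut at the largest gap in merge heights.
    """
    if height_cutoff is not None and height_cutoff <= 0:
        raise ConfigurationError("height_cutoff must be positive")
    if corr.isna().any().any():
        raise PipelineError("call_clusters: correlation matrix has missing cells")
    if linkage not in {"average", "complete"}:
        raise ConfigurationError(f"unsupported linkage {linkage!r}")
    dist = 1.0 - corr.to_numpy(dtype=float)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    if height_cutoff is None:
        height_cutoff = _auto_cutoff(Z[:, 2])
    labels = hierarchy.fcluster(Z, t=height_cutoff, criterion="distance")
    coph = squareform(hierarchy.cophenet(Z))
    datasets = list(corr.columns)
    rho = corr.to_numpy(dtype=float)
    clusters: list[DatasetCluster] = []
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_size:
            continue
        pair_rho = rho[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        positive_fraction = float(np.mean(pair_rho > 0))
        if positive_fraction < dominance:
            continue
        merge_height = float(coph[np.ix_(idx, idx)].max())
        clusters.append(
            DatasetCluster(
                label=f"C{len(clusters) + 1}",
                members=[datasets[i] for i in idx],
                merge_height=merge_height,
                positive_fraction=positive_fraction,
            )
        )
    return clusters


def embed_2d(
    matrix: pd.DataFrame, n_neighbors: int = 15, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """UMAP embedding of dataset columns (Euclidean distance, fixed seed)."""
    n_datasets = matrix.shape[1]
    if n_datasets < n_neighbors + 1:
        raise PipelineError(
            f"embed_2d: need at least n_neighbors+1={n_neighbors + 1} datasets, "
            f"got {n_datasets}"
        )
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, n_components=2, metric="euclidean", random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(matrix.T.to_numpy(dtype=float))
    return {
        dataset: (float(x), float(y))
        for dataset, (x, y) in zip(matrix.columns, coords)
    }


def clusters_to_frame(clusters: list[DatasetCluster]) -> pd.DataFrame:
    rows = [
        {
            "dataset_id": member,
            "cluster_label": c.label,
            "merge_height": c.merge_height,
            "positive_fraction": c.positive_fraction,
        }
        for c in clusters
        for member in c.members
    ]
    return pd.DataFrame(rows, columns=["dataset_id", "cluster_label", "merge_height", "positive_fraction"])
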