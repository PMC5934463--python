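r"""Correlation-based average-linkage (UPGMA) hierarchical clustering.

Channels are grouped by the dissimilarity ``D_ij = 1 - |R_ij|``: perfectly
(anti-)correlated pairs are at distance 0, uncorrelated pairs at distance 1.
Agglomeration starts from singletons and repeatedly merges the pair of
clusters with the smallest inter-cluster distance, updating distances by the
size-weighted average over all cross-cluster member pairs,

.. math:: D_{X,Y} = \frac{\sum_{x \in X} \sum_{y \in Y} D_{x,y}}{n_X n_Y},

i.e. UPGMA.  Cutting the dendrogram at a height ``h`` (merges at exactly
``h`` are applied) yields spatial regions of similar functional behaviour;
the normalized cluster count (clusters / channels, singletons counted)
swept over a cut-off grid and integrated (trapezoid) gives a cut-off-free
complexity index — high when the record fragments into many small regions,
``1/n`` when every channel belongs to one cluster.

The agglomeration itself is delegated to :mod:`scipy.cluster.hierarchy`
(``linkage(method="average")`` / ``fcluster``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .correlation import CorrelationMatrix
from .errors import ParameterError

#: Default cut-off grid, mirroring the threshold grid.
DEFAULT_CUTOFF_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal matrix with entries in [0, 1]."""

    D: np.ndarray
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = self.D.shape[0]
        if self.D.ndim != 2 or self.D.shape[1] != n:
            raise ParameterError("D must be square")
        if not np.allclose(self.D, self.D.T):
            raise ParameterError("D must be symmetric")
        if np.any(self.D < -1e-12) or np.any(self.D > 1 + 1e-12):
            raise ParameterError("dissimilarities must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise ParameterError("D must have zero diagonal")
        if not self.channel_ids:
            self.channel_ids = list(range(n))

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class Dendrogram:
    """Ordered merge list from agglomerative clustering.

    ``merges`` is the scipy linkage matrix: each row
    ``(cluster_a, cluster_b, height, new_size)`` merges two clusters
    (original observations are 0..n-1; row i creates cluster n+i).
    """

    merges: np.ndarray
    n_leaves: int
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ParameterError("a dendrogram on n leaves must have n-1 merges")
        if not self.channel_ids:
            self.channel_ids = list(range(self.n_leaves))

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def dissimilarity(R: CorrelationMatrix | np.ndarray) -> DissimilarityMatrix:
    """``D = 1 - |R|``, clipped into [0, 1] with an exactly zero diagonal."""
    mat = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    ids = list(R.channel_ids) if isinstance(R, CorrelationMatrix) else []
    D = 1.0 - np.abs(mat)
    np.clip(D, 0.0, 1.0, out=D)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D=D, channel_ids=ids)


def average_linkage(D: DissimilarityMatrix | np.ndarray) -> Dendrogram:
    """UPGMA agglomeration of a dissimilarity matrix."""
    if not isinstance(D, DissimilarityMatrix):
        D = DissimilarityMatrix(D=np.asarray(D, dtype=float))
    if D.n < 2:
        raise ParameterError("clustering needs at least 2 channels")
    Z = linkage(squareform(D.D, checks=False), method="average")
    return Dendrogram(merges=Z, n_leaves=D.n, channel_ids=list(D.channel_ids))


def cut_dendrogram(dendrogram: Dendrogram, h: float) -> np.ndarray:
    """Flat cluster labels from applying all merges of height <= ``h``.

    Labels are 0-based and stable: renumbered by first channel occurrence.
    """
    if h < 0:
        raise ParameterError("cut height must be non-negative")
    raw = fcluster(dendrogram.merges, t=h, criterion="distance")
    labels = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    return labels


def cluster_sizes(labels: np.ndarray) -> np.ndarray:
    return np.bincount(np.asarray(labels, dtype=int))


def cluster_count_curve(
    D: DissimilarityMatrix | np.ndarray,
    h_grid: np.ndarray = DEFAULT_CUTOFF_GRID,
) -> tuple[np.ndarray, float]:
    """Normalized cluster count across a cut-off grid and its AUC.

    At each cut-off the number of flat clusters (singletons counted as
    clusters) is divided by the channel count; the curve is non-increasing
    in ``h`` and integrated by the trapezoidal rule.
    """
    grid = np.asarray(h_grid, dtype=float)
    if grid.size < 2:
        raise ParameterError("h_grid needs at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("h_grid must be strictly increasing")
    dend = average_linkage(D)
    n = dend.n_leaves
    counts = np.array(
        [np.unique(fcluster(dend.merges, t=h, criterion="distance")).size for h in grid],
        dtype=float,
    )
    normalized = counts / n
    return normalized, float(np.trapezoid(normalized, grid))


def cluster_map(
    dendrogram: Dendrogram,
    h: float,
    coordinates: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Per-channel cluster assignment table for plotting.

    Columns: channel_id, x, y (NaN if no layout), label, is_singleton.
    Singletons are flagged so a display layer can mark channels that do not
    form a cluster.
    """
    import pandas as pd

    labels = cut_dendrogram(dendrogram, h)
    sizes = cluster_sizes(labels)
    if coordinates is None:
        coordinates = np.full((len(labels), 2), np.nan)
    coordinates = np.asarray(coordinates, dtype=float)
    return pd.DataFrame(
        {
            "channel_id": dendrogram.channel_ids,
            "x": coordinates[:, 0],
            "y": coordinates[:, 1],
            "label": labels,
            "is_singleton": sizes[labels] == 1,
        }
    )
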