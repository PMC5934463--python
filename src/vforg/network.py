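r"""Functional-network construction and graph measures.

The correlation matrix is thresholded on |R| into a weighted undirected
graph with no self connections: ``A_ij = 1`` iff ``i != j`` and
``|R_ij| >= theta`` (ties kept, so theta = 0 gives the complete graph), and
``W_ij = |R_ij| A_ij``.  Absolute values are used as weights because the
thresholding is defined on correlation magnitude and triangle intensities
need non-negative weights; the signed matrix is retained upstream.

Measures:

- connection density ``rho = 2 n_e / (n_v (n_v - 1))``;
- node strength ``S_i = sum_j a_ij w_ij``;
- weighted clustering coefficient in the triangle-intensity form
  ``C_i = 2 l_i / (k_i (k_i - 1))`` with
  ``l_i = sum_{ {j,h} } (w'_ij w'_jh w'_hi)^{1/3}`` over unordered neighbor
  pairs, weights max-normalized (``w' = W / max W``).  Matrix form:
  ``2 l = diag((W'^{1/3})^3)``, so for binary weights this reduces to the
  classic unweighted clustering coefficient;
- AUC over a threshold sweep (trapezoid on a 0:0.05:1 grid by default),
  a threshold-free summary of interconnectedness;
- hub nodes: strength strictly greater than the network mean strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .correlation import CorrelationMatrix
from .errors import ParameterError

#: Default threshold grid: 0 to 1 with an increment of 0.05.
DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)


@dataclass
class FunctionalNetwork:
    """Thresholded weighted undirected graph (zero diagonal)."""

    A: np.ndarray
    W: np.ndarray
    threshold: float
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=bool)
        self.W = np.asarray(self.W, dtype=float)
        if not self.channel_ids:
            self.channel_ids = list(range(self.A.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (channel_id_i, channel_id_j, weight), i < j."""
        ii, jj = np.nonzero(np.triu(self.A, k=1))
        ids = self.channel_ids
        return [(ids[i], ids[j], float(self.W[i, j])) for i, j in zip(ii, jj)]


@dataclass
class GraphMeasures:
    rho: float
    strength: np.ndarray
    clustering_local: np.ndarray
    clustering_avg: float


def _as_matrix(R: CorrelationMatrix | np.ndarray) -> np.ndarray:
    return R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)


def threshold_network(R: CorrelationMatrix | np.ndarray, theta: float) -> FunctionalNetwork:
    """Threshold |R| at ``theta`` (inclusive) into a functional network."""
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {theta}")
    mat = _as_matrix(R)
    ids = list(R.channel_ids) if isinstance(R, CorrelationMatrix) else []
    absR = np.abs(mat)
    # weights first (entries under theta zeroed), adjacency = nonzero weights,
    # so exactly-zero correlations never form edges even at theta = 0
    A = (absR >= theta) & (absR > 0.0)
    np.fill_diagonal(A, False)
    W = np.where(A, absR, 0.0)
    return FunctionalNetwork(A=A, W=W, threshold=theta, channel_ids=ids)


def connection_density(network: FunctionalNetwork) -> float:
    """Fraction of realized edges out of all possible node pairs."""
    n = network.n_nodes
    if n < 2:
        raise ParameterError("connection density requires at least 2 nodes")
    return 2.0 * network.n_edges / (n * (n - 1))


def node_strength(network: FunctionalNetwork) -> np.ndarray:
    """Per-node sum of incident edge weights."""
    return (network.W * network.A).sum(axis=1)


def clustering_coefficients(network: FunctionalNetwork) -> tuple[np.ndarray, float]:
    """Local weighted clustering coefficients and their network average.

    Weights are normalized by the largest weight in the network before the
    geometric-mean triangle intensities are summed.  Nodes of degree < 2
    have coefficient 0; an edgeless network has average 0.
    """
    W = network.W
    k = network.A.sum(axis=1).astype(float)
    n = network.n_nodes
    wmax = W.max() if W.size else 0.0
    if wmax == 0.0:
        return np.zeros(n), 0.0
    Wn = (W / wmax) ** (1.0 / 3.0)
    # diag((W'^{1/3})^3)_i = 2 * sum over unordered neighbor pairs {j,h}
    two_l = np.einsum("ij,jh,hi->i", Wn, Wn, Wn)
    denom = k * (k - 1)
    C_local = np.divide(two_l, denom, out=np.zeros(n), where=denom > 0)
    return C_local, float(C_local.mean())


_MEASURES: dict[str, Callable[[FunctionalNetwork], float]] = {
    "density": connection_density,
    "avg_clustering": lambda net: clustering_coefficients(net)[1],
}


def measure_over_thresholds(
    R: CorrelationMatrix | np.ndarray,
    measure: str,
    theta_grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
) -> np.ndarray:
    """Evaluate a graph measure at every threshold of the grid."""
    if measure not in _MEASURES:
        raise ParameterError(f"unknown measure {measure!r}; choose from {sorted(_MEASURES)}")
    grid = np.asarray(theta_grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid[0] < 0 or grid[-1] > 1:
        raise ParameterError("theta_grid must be strictly increasing within [0, 1]")
    fn = _MEASURES[measure]
    return np.array([fn(threshold_network(R, th)) for th in grid])


def auc_over_thresholds(
    R: CorrelationMatrix | np.ndarray,
    measure: str,
    theta_grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
) -> float:
    """Trapezoidal area under measure(theta) over the threshold grid."""
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size < 2:
        raise ParameterError("theta_grid needs at least 2 points")
    vals = measure_over_thresholds(R, measure, grid)
    return float(np.trapezoid(vals, grid))


def hub_nodes(network: FunctionalNetwork) -> set[int]:
    """Highly connected nodes: strength strictly above the network mean.

    Returns channel ids.  Uniform-strength networks (including the empty
    graph) have no hubs under the strict inequality.
    """
    S = node_strength(network)
    if S.size == 0:
        return set()
    mean = S.mean()
    return {network.channel_ids[i] for i in np.nonzero(S > mean)[0]}
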