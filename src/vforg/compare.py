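"""Agreement between complexity measures.

Two tools for relating the cluster-count complexity index to an externally
computed fibrillation-complexity series (e.g. per-recording phase-
singularity counts, which this package deliberately does not compute):

- ``rsquared``: coefficient of determination of a simple linear regression
  of one aligned series on the other (equal to the squared Pearson
  correlation in the simple-regression case);
- ``pca_epoch_features``: per-epoch PCA of time-varying complexity
  courses, treating recordings as observations and time points within the
  epoch as variables, projecting each recording onto the first two
  principal components so recordings with similar complexity dynamics fall
  near each other in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DegenerateSignalError, ParameterError


@dataclass
class MeasurePair:
    """Two aligned scalar series to be regressed on one another."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ParameterError("series must have equal length")
        if self.x.size < 3:
            raise ParameterError("need at least 3 aligned points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ParameterError("series must be finite")


def rsquared(pair: MeasurePair) -> float:
    """Coefficient of determination of the simple regression of y on x."""
    if np.var(pair.x) == 0:
        raise DegenerateSignalError("R-squared undefined for constant x")
    if np.var(pair.y) == 0:
        return 0.0
    result = stats.linregress(pair.x, pair.y)
    return float(result.rvalue**2)


def align_per_second(times_s: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average a series into 1 s bins (used to align window-based series
    with per-second count series)."""
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    bins = np.floor(times_s).astype(int)
    uniq = np.unique(bins)
    means = np.array([values[bins == b].mean() for b in uniq])
    return uniq.astype(float) + 0.5, means


def pca_epoch_features(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First two principal-component scores per recording.

    ``matrix`` has rows = time points within the epoch and columns =
    recordings; recordings are the observations, so the matrix is
    transposed and column-centred (over recordings) before the
    decomposition.  The sign of each component is fixed by making its
    largest-magnitude loading positive.

    Returns ``(scores, explained_variance_ratio, components)`` where
    ``scores`` is (n_recordings, 2) and ``components`` is (2, n_times).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ParameterError("need at least 2 time points and 2 recordings")
    X = matrix.T  # observations = recordings
    if np.allclose(X, X[0]):
        raise DegenerateSignalError("constant feature matrix has no principal axes")
    n_comp = min(2, min(X.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_
    for c in range(n_comp):
        j = np.argmax(np.abs(components[c]))
        if components[c, j] < 0:
            components[c] *= -1
            scores[:, c] *= -1
    if n_comp < 2:  # rank-1 data: pad the second component with zeros
        scores = np.column_stack([scores, np.zeros(len(scores))])
        components = np.vstack([components, np.zeros(components.shape[1])])
        evr = np.array([pca.explained_variance_ratio_[0], 0.0])
    else:
        evr = pca.explained_variance_ratio_.copy()
    return scores, evr, components
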