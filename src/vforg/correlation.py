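r"""Lag-searched normalized cross-correlation and the organization measure.

The linear coupling between two channels :math:`y_i`, :math:`y_j` is the
normalized cross-correlation evaluated over a symmetric lag set
:math:`\tau \in \{-d, \dots, 0, \dots, d\}`:

.. math::

    r_{i,j}(\tau) = \frac{\sum_{t=1}^{N-\tau} y_i(t)\, y_j(t+\tau)}
                         {\sqrt{\sum_t y_i(t)^2}\,\sqrt{\sum_t y_j(t)^2}},
    \qquad r_{i,j}(-\tau) = r_{j,i}(\tau).

Note the denominator uses full-length norms for every lag (implemented
literally; |r| can slightly understate alignment at large lags).  The
correlation matrix keeps the *signed* value at the lag of maximum absolute
correlation,

.. math:: R_{i,j} = r_{i,j}\bigl(\arg\max_\tau |r_{i,j}(\tau)|\bigr),

and the global organization of an n-channel record is the normalized
Frobenius norm :math:`c = \lVert R \rVert_F / n`, which ranges from
:math:`1/\sqrt{n}` (identity R, no coupling) to 1 (perfect coupling).

The total lag window ``2d`` is conventionally set to the maximum average
activation cycle length, itself estimated as the inverse of the mean
dominant frequency across channels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import SignalEnsemble
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LagSpec:
    """Symmetric lag window: lags run over ``-d .. 0 .. d`` samples."""

    d: int
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ParameterError(f"maximum lag must be non-negative, got {self.d}")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.d, self.d + 1)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of signed peak-|r| lagged correlations."""

    R: np.ndarray
    channel_ids: list[int] = field(default_factory=list)
    lag_at_peak: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = self.R.shape[0]
        if self.R.ndim != 2 or self.R.shape[1] != n:
            raise ParameterError("R must be square")
        if not self.channel_ids:
            self.channel_ids = list(range(n))
        if not np.allclose(self.R, self.R.T):
            raise ParameterError("R must be symmetric")
        if np.max(np.abs(self.R)) > 1.0 + 1e-9:
            raise ParameterError("correlation entries must satisfy |R_ij| <= 1")

    @property
    def n(self) -> int:
        return self.R.shape[0]


def lag_window_from_cycle_length(max_cycle_ms: float, fs: float) -> LagSpec:
    """Lag window whose total width ``2d`` covers the maximum average
    activation cycle length.

    ``d = ceil(round(max_cycle_ms * fs / 1000) / 2)`` — the cycle length is
    first expressed in samples (nearest integer), then halved, rounding up so
    an odd sample count never shortens the window.  A 232 ms cycle at 1 kHz
    gives d = 116 samples (a +/-116 ms search window).
    """
    if max_cycle_ms <= 0:
        raise ParameterError("cycle length must be positive")
    n_samples = round(max_cycle_ms * fs / 1000.0)
    return LagSpec(d=math.ceil(n_samples / 2), fs=fs)


def _validate_pair(y_i: np.ndarray, y_j: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    y_i = np.asarray(y_i, dtype=float).ravel()
    y_j = np.asarray(y_j, dtype=float).ravel()
    if y_i.shape != y_j.shape:
        raise ParameterError("signals must have equal length")
    if not (np.all(np.isfinite(y_i)) and np.all(np.isfinite(y_j))):
        raise ParameterError("signals must be finite")
    if d >= y_i.size:
        raise ParameterError(f"maximum lag {d} must be smaller than record length {y_i.size}")
    return y_i, y_j


def cross_correlation(y_i: np.ndarray, y_j: np.ndarray, lagspec: LagSpec) -> np.ndarray:
    """Normalized cross-correlation sequence ``r(tau)`` for ``tau = -d..d``.

    Positive lags are the truncated inner product over ``t = 1..N-tau``
    divided by the product of full-length norms; negative lags use the
    identity ``r_ij(-tau) = r_ji(tau)``.  A zero-variance signal yields
    ``r == 0`` (flagged in the log) rather than NaN.
    """
    y_i, y_j = _validate_pair(y_i, y_j, lagspec.d)
    d = lagspec.d
    n = y_i.size
    norm = math.sqrt(float(y_i @ y_i)) * math.sqrt(float(y_j @ y_j))
    r = np.zeros(2 * d + 1)
    if norm == 0.0:
        logger.warning("degenerate (zero-variance) signal: correlation set to 0")
        return r
    for tau in range(d + 1):
        r[d + tau] = float(y_i[: n - tau] @ y_j[tau:]) / norm
        r[d - tau] = float(y_j[: n - tau] @ y_i[tau:]) / norm
    return r


def correlation_matrix(
    ensemble: SignalEnsemble | np.ndarray,
    lagspec: LagSpec,
    channel_ids: list[int] | None = None,
) -> CorrelationMatrix:
    """Signed peak-|r| correlation matrix over all channel pairs.

    For every ordered pair the lag of maximum |r| is searched over
    ``-d..d``; ties are broken toward the smallest |tau| and, among
    ``+/-tau``, toward the negative lag (applied on the upper-triangle
    orientation; the matrix is mirrored, so symmetry is exact).  The
    diagonal is exactly 1.  Zero-variance channels get zero correlation with
    every other channel and are flagged in ``degenerate``.
    """
    if isinstance(ensemble, SignalEnsemble):
        Y = ensemble.data
        ids = list(ensemble.channel_ids)
    else:
        Y = np.asarray(ensemble, dtype=float)
        ids = channel_ids or list(range(Y.shape[0]))
    n_ch, n = Y.shape
    if n_ch < 2:
        raise ParameterError("correlation matrix needs at least 2 channels")
    d = lagspec.d
    if d >= n:
        raise ParameterError(f"maximum lag {d} must be smaller than record length {n}")

    norms = np.sqrt(np.einsum("ij,ij->i", Y, Y))
    degenerate = norms == 0.0
    if degenerate.any():
        logger.warning("%d degenerate channel(s); correlations set to 0", degenerate.sum())
    inv = np.zeros_like(norms)
    inv[~degenerate] = 1.0 / norms[~degenerate]
    scale = np.outer(inv, inv)

    # tau = 0 first, then each tau with the negative orientation before the
    # positive one; strict ">" updates make earlier candidates win ties.
    M0 = (Y @ Y.T) * scale
    best = M0.copy()
    best_abs = np.abs(M0)
    best_lag = np.zeros((n_ch, n_ch), dtype=int)
    for tau in range(1, d + 1):
        M = (Y[:, : n - tau] @ Y[:, tau:].T) * scale
        for cand, lag in ((M.T, -tau), (M, tau)):
            mask = np.abs(cand) > best_abs
            if mask.any():
                best[mask] = cand[mask]
                best_abs[mask] = np.abs(cand[mask])
                best_lag[mask] = lag

    # mirror the i<j orientation for exact symmetry
    R = np.triu(best, k=1)
    R = R + R.T
    lag_peak = np.triu(best_lag, k=1)
    lag_peak = lag_peak + lag_peak.T
    np.fill_diagonal(R, 1.0)
    np.clip(R, -1.0, 1.0, out=R)
    return CorrelationMatrix(R=R, channel_ids=ids, lag_at_peak=lag_peak, degenerate=degenerate)


def organization_measure(R: CorrelationMatrix | np.ndarray) -> float:
    """Normalized Frobenius norm ``c = ||R||_F / n`` of a correlation matrix.

    Bounded by ``1/sqrt(n)`` (unit diagonal only) and 1 (all entries of
    magnitude one).
    """
    mat = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    n = mat.shape[0]
    return float(np.linalg.norm(mat, ord="fro") / n)
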