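r"""Sliding-window measure series and epoch-knotted piecewise-linear trends.

Any scalar measure of a correlation matrix can be tracked through time by
recomputing the matrix on overlapping windows (1000 samples with a
500-sample hop by default, so a 210 s record at 1 kHz yields 420 segments)
and fitting the resulting series with a continuous linear spline whose
knots sit at the epoch onsets:

.. math:: y(t) = \beta_0 + \beta_1 t + \sum_k \gamma_k (t - t_k)_+ ,

estimated by ordinary least squares.  The intercept and the per-epoch slope
changes :math:`\gamma_k` summarize how organization evolves across the
experimental stages; means and sample SDs across recordings provide the
group-level summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .correlation import CorrelationMatrix, LagSpec, correlation_matrix
from .ensemble import SignalEnsemble
from .errors import ParameterError

logger = logging.getLogger(__name__)

#: Default analysis window: 1000 samples with 500-sample overlap.
WINDOW_LEN = 1000
WINDOW_HOP = 500


@dataclass
class WindowedSeries:
    """Per-window values of a scalar measure."""

    starts: np.ndarray  # samples
    ends: np.ndarray  # samples (exclusive)
    t_center_s: np.ndarray
    values: np.ndarray
    measure: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrendFit:
    """Continuous linear-spline fit with fixed knots."""

    intercept: float
    slope: float
    slope_changes: np.ndarray
    knots_s: np.ndarray
    times_s: np.ndarray
    fitted: np.ndarray
    residual_sd: float = 0.0

    def predict(self, times_s: np.ndarray) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        y = self.intercept + self.slope * t
        for gamma, knot in zip(self.slope_changes, self.knots_s):
            y = y + gamma * np.clip(t - knot, 0.0, None)
        return y

    def segment_slopes(self) -> np.ndarray:
        """Slope within each inter-knot segment (cumulative sums of changes)."""
        return self.slope + np.concatenate([[0.0], np.cumsum(self.slope_changes)])


def sliding_windows(n_samples: int, window_len: int, hop: int) -> list[tuple[int, int]]:
    """Window segments ``[start, end)`` starting at 0, hop, 2*hop, ...

    A truncated final window is retained iff its length is at least ``hop``
    (this convention makes a 210 000-sample record with 1000/500 windowing
    yield exactly 420 segments).
    """
    if not 0 < hop <= window_len:
        raise ParameterError("need 0 < hop <= window_len")
    if window_len > n_samples and n_samples < hop:
        raise ParameterError("record shorter than one hop")
    out = []
    for start in range(0, n_samples, hop):
        end = min(start + window_len, n_samples)
        if end - start >= hop or end - start == window_len:
            out.append((start, end))
    return out


def windowed_measure(
    ensemble: SignalEnsemble,
    lagspec: LagSpec,
    measure_fn: Callable[[CorrelationMatrix], float],
    window_len: int = WINDOW_LEN,
    hop: int = WINDOW_HOP,
    measure_name: str = "",
) -> WindowedSeries:
    """Recompute the correlation matrix per window and apply ``measure_fn``.

    Windows too short to host the lag search (< 2d + 2 samples) are skipped
    with a warning rather than zero-padded.
    """
    windows = sliding_windows(ensemble.n_samples, window_len, hop)
    starts, ends, centers, values = [], [], [], []
    min_len = 2 * lagspec.d + 2
    for start, end in windows:
        if end - start < min_len:
            logger.warning(
                "window [%d, %d) shorter than 2d+2 = %d samples; skipped",
                start, end, min_len,
            )
            continue
        R = correlation_matrix(
            ensemble.slice_samples(start, end), lagspec, list(ensemble.channel_ids)
        )
        starts.append(start)
        ends.append(end)
        centers.append((start + end) / 2.0 / ensemble.fs)
        values.append(measure_fn(R))
    return WindowedSeries(
        starts=np.array(starts, dtype=int),
        ends=np.array(ends, dtype=int),
        t_center_s=np.array(centers),
        values=np.array(values, dtype=float),
        measure=measure_name,
    )


def spline_design(times: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix [1, t, (t - t_k)_+ ...] of the continuous linear spline."""
    t = np.asarray(times, dtype=float)
    cols = [np.ones_like(t), t]
    for knot in knots:
        cols.append(np.clip(t - knot, 0.0, None))
    return np.column_stack(cols)


def piecewise_linear_fit(
    times: np.ndarray, values: np.ndarray, knots: Sequence[float]
) -> TrendFit:
    """Least-squares continuous linear spline with fixed knots.

    Knots must be strictly increasing; the design must have full column
    rank (at least two points per segment in practice).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if t.shape != y.shape:
        raise ParameterError("times and values must have equal length")
    if knots.size and np.any(np.diff(knots) <= 0):
        raise ParameterError("knots must be strictly increasing")
    X = spline_design(t, knots)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ParameterError(
            "rank-deficient spline design: too few points per segment"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    dof = max(len(y) - X.shape[1], 1)
    residual_sd = float(np.sqrt(np.sum((y - fitted) ** 2) / dof))
    return TrendFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        slope_changes=beta[2:].copy(),
        knots_s=knots,
        times_s=t,
        fitted=fitted,
        residual_sd=residual_sd,
    )


def epoch_knots(epoch_schedule: Sequence[tuple[str, float, float]]) -> np.ndarray:
    """Interior epoch onsets, used as spline knots."""
    return np.array([start for _, start, _ in epoch_schedule[1:]], dtype=float)


def fit_epoch_trend(series: WindowedSeries, epoch_schedule) -> TrendFit:
    """Piecewise-linear fit of a windowed series with epoch-onset knots."""
    return piecewise_linear_fit(series.t_center_s, series.values, epoch_knots(epoch_schedule))


def epoch_summary(fits: Sequence[TrendFit]) -> "pd.DataFrame":
    """Mean and sample SD of intercept and slope changes across recordings.

    A single recording is reported with SD 0 and ``single_recording=True``
    in the frame attrs.  All fits must share the same knots.
    """
    import pandas as pd

    if not fits:
        raise ParameterError("need at least one fit")
    knots = fits[0].knots_s
    for f in fits[1:]:
        if not np.array_equal(f.knots_s, knots):
            raise ParameterError("all fits must share the same knots")
    params = np.array(
        [[f.intercept, f.slope, *f.slope_changes] for f in fits], dtype=float
    )
    names = ["intercept", "slope"] + [f"slope_change_at_{k:g}s" for k in knots]
    mean = params.mean(axis=0)
    sd = params.std(axis=0, ddof=1) if len(fits) > 1 else np.zeros(params.shape[1])
    frame = pd.DataFrame({"parameter": names, "mean": mean, "sd": sd})
    frame.attrs["n_recordings"] = len(fits)
    frame.attrs["single_recording"] = len(fits) == 1
    return frame
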