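"""Detrending and channel-quality screening.

Two preprocessing steps precede any coupling analysis:

1. piecewise linear detrending (independent least-squares line removed from
   each non-overlapping segment), which strips slow respiratory drift and
   leaves each segment with approximately zero mean;
2. channel exclusion — a channel is kept only if its dominant frequency
   (modal frequency of the Welch power spectrum, 3000-sample Hann windows
   with 1500-sample overlap) lies in the 2-20 Hz fibrillation band and its
   RMS amplitude is not negligibly small.  The amplitude rule automates a
   visual near-zero-amplitude screen as RMS >= 5% of the median channel RMS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .ensemble import SignalEnsemble
from .errors import DegenerateSignalError, ParameterError

logger = logging.getLogger(__name__)

#: Inclusion band for dominant frequencies, Hz.
DF_BAND = (2.0, 20.0)
#: Welch parameters for dominant-frequency estimation.
WELCH_NPERSEG = 3000
WELCH_NOVERLAP = 1500
#: Lower edge of the DF search band, Hz (the 2-20 Hz rule is the inclusion
#: filter, not the search bound, so out-of-band DFs are still reported).
DF_SEARCH_FLOOR = 0.5
#: Amplitude floor as a fraction of the median channel RMS.
RMS_FLOOR_FRAC = 0.05


@dataclass
class ChannelMask:
    """Per-channel keep decision with one exclusion reason per dropped channel."""

    keep: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)
    df_hz: np.ndarray | None = None
    rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        for idx in np.nonzero(~self.keep)[0]:
            if int(idx) not in self.reasons:
                raise ParameterError(f"excluded channel {idx} has no reason")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_records(self, channel_ids: list[int]) -> list[dict]:
        out = []
        for i, cid in enumerate(channel_ids):
            out.append(
                {
                    "channel_id": cid,
                    "keep": bool(self.keep[i]),
                    "reason": self.reasons.get(i),
                    "df_hz": None if self.df_hz is None or np.isnan(self.df_hz[i]) else float(self.df_hz[i]),
                    "rms": None if self.rms is None else float(self.rms[i]),
                }
            )
        return out


def detrend_piecewise_linear(
    ensemble: SignalEnsemble, segment_len_samples: int = 1000
) -> SignalEnsemble:
    """Remove an independent least-squares line from each non-overlapping
    segment of every channel.

    The final segment may be shorter.  Idempotent to floating tolerance.
    """
    if segment_len_samples < 2:
        raise ParameterError("segment length must be at least 2 samples")
    n = ensemble.n_samples
    if segment_len_samples > n:
        raise ParameterError(
            f"segment length {segment_len_samples} exceeds record length {n}"
        )
    bp = np.arange(segment_len_samples, n, segment_len_samples)
    # drop a trailing length-1 segment: a line through one point is ill-posed
    if bp.size and n - bp[-1] < 2:
        bp = bp[:-1]
    detrended = sps.detrend(ensemble.data, axis=1, type="linear", bp=bp)
    return SignalEnsemble(
        data=detrended,
        fs=ensemble.fs,
        channel_ids=list(ensemble.channel_ids),
        epoch_schedule=list(ensemble.epoch_schedule),
    )


def dominant_frequency(
    signal: np.ndarray,
    fs: float,
    welch_nperseg: int = WELCH_NPERSEG,
    welch_noverlap: int = WELCH_NOVERLAP,
    search_floor_hz: float = DF_SEARCH_FLOOR,
) -> float:
    """Modal frequency (Hz) of the Welch power spectral density.

    Mean-averaged Hann-tapered periodograms; the argmax is searched over
    [``search_floor_hz``, fs/2).  All-zero input raises
    :class:`DegenerateSignalError`.
    """
    y = np.asarray(signal, dtype=float).ravel()
    if y.size < welch_nperseg:
        raise ParameterError(
            f"signal length {y.size} shorter than Welch segment {welch_nperseg}"
        )
    if not np.any(y):
        raise DegenerateSignalError("dominant frequency undefined for all-zero signal")
    freqs, psd = sps.welch(
        y,
        fs=fs,
        window="hann",
        nperseg=welch_nperseg,
        noverlap=welch_noverlap,
        detrend=False,
        average="mean",
    )
    band = (freqs >= search_floor_hz) & (freqs < fs / 2)
    if not band.any():
        raise ParameterError("empty dominant-frequency search band")
    return float(freqs[band][np.argmax(psd[band])])


def select_channels(
    ensemble: SignalEnsemble,
    df_band: tuple[float, float] = DF_BAND,
    rms_floor_frac: float = RMS_FLOOR_FRAC,
    welch_nperseg: int = WELCH_NPERSEG,
    welch_noverlap: int = WELCH_NOVERLAP,
) -> ChannelMask:
    """Quality screen on a detrended ensemble.

    A channel is kept iff its RMS is at least ``rms_floor_frac`` of the
    median channel RMS *and* its dominant frequency lies in ``df_band``
    (inclusive).  Near-zero channels are excluded as ``low_amplitude``
    without a DF estimate; otherwise out-of-band DFs give
    ``df_out_of_band``.  An empty keep-set is legal and logged.
    """
    n_ch = ensemble.n_channels
    rms = np.sqrt(np.mean(ensemble.data**2, axis=1))
    floor = rms_floor_frac * np.median(rms)
    keep = np.ones(n_ch, dtype=bool)
    reasons: dict[int, str] = {}
    df = np.full(n_ch, np.nan)
    lo, hi = df_band
    for i in range(n_ch):
        if rms[i] < floor or rms[i] == 0.0:
            keep[i] = False
            reasons[i] = "low_amplitude"
            continue
        df[i] = dominant_frequency(
            ensemble.data[i], ensemble.fs, welch_nperseg, welch_noverlap
        )
        if not lo <= df[i] <= hi:
            keep[i] = False
            reasons[i] = "df_out_of_band"
    if not keep.any():
        logger.warning("channel selection excluded every channel")
    else:
        logger.info("kept %d / %d channels", int(keep.sum()), n_ch)
    return ChannelMask(keep=keep, reasons=reasons, df_hz=df, rms=rms)
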