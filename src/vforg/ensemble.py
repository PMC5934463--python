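"""Core in-memory containers for multichannel electrogram-like recordings.

A :class:`SignalEnsemble` is the package's central object: a channels x
samples matrix with a sampling rate, channel identifiers and an epoch
schedule (named, ordered, non-overlapping time intervals such as the seven
30 s stages of a perfusion/ischaemia/reflow protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: name, start (s), end (s)
Epoch = tuple[str, float, float]

#: The canonical seven-stage schedule: 30 s control perfusion, five 30 s
#: ischaemia epochs, 30 s reflow.
DEFAULT_VF_EPOCHS: tuple[Epoch, ...] = (
    ("Control", 0.0, 30.0),
    ("Isch1", 30.0, 60.0),
    ("Isch2", 60.0, 90.0),
    ("Isch3", 90.0, 120.0),
    ("Isch4", 120.0, 150.0),
    ("Isch5", 150.0, 180.0),
    ("Reflow", 180.0, 210.0),
)


def validate_epoch_schedule(epochs: list[Epoch], duration_s: float) -> None:
    """Raise :class:`ParameterError` unless epochs are ordered,
    non-overlapping and within the record length."""
    prev_end = 0.0
    for name, start, end in epochs:
        if start < prev_end - 1e-9:
            raise ParameterError(
                f"epoch {name!r} starts at {start}s before previous end {prev_end}s"
            )
        if end <= start:
            raise ParameterError(f"epoch {name!r} has non-positive length")
        if end > duration_s + 1e-9:
            raise ParameterError(
                f"epoch {name!r} ends at {end}s beyond record length {duration_s}s"
            )
        prev_end = end


@dataclass
class SignalEnsemble:
    """Multichannel recording: ``data`` is channels x samples.

    Parameters
    ----------
    data
        Real matrix, one row per channel, arbitrary amplitude units.
    fs
        Sampling rate in Hz, strictly positive.
    channel_ids
        Integer label per channel; defaults to ``0..n-1``.
    epoch_schedule
        List of ``(name, start_s, end_s)``; defaults to one epoch spanning
        the record.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[int] = field(default_factory=list)
    epoch_schedule: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_ids:
            self.channel_ids = list(range(self.data.shape[0]))
        if len(self.channel_ids) != self.data.shape[0]:
            raise ParameterError("channel_ids length must match channel count")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel ids must be unique")
        if not self.epoch_schedule:
            self.epoch_schedule = [("all", 0.0, self.duration_s)]
        self.epoch_schedule = [tuple(e) for e in self.epoch_schedule]
        validate_epoch_schedule(self.epoch_schedule, self.duration_s)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs

    def subset(self, keep: np.ndarray) -> "SignalEnsemble":
        """Return an ensemble restricted to the channels where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_channels,):
            raise ParameterError("keep mask length must match channel count")
        ids = [c for c, k in zip(self.channel_ids, keep) if k]
        return SignalEnsemble(
            data=self.data[keep].copy(),
            fs=self.fs,
            channel_ids=ids,
            epoch_schedule=list(self.epoch_schedule),
        )

    def slice_samples(self, start: int, end: int) -> np.ndarray:
        """Raw data view for samples ``start:end`` (no epoch bookkeeping)."""
        return self.data[:, start:end]
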