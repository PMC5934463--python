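"""Synthetic multichannel electrogram-like ensembles with known structure.

Real epicardial fibrillation recordings (hundreds of channels, 1 kHz,
oscillatory content with dominant frequencies in the 2-20 Hz band, slow
respiratory drift, measurement noise, spatially clustered coupling) are not
generally shareable, so this module generates stand-ins with controllable
ground truth for end-to-end testing and parameter-recovery studies.

Signal model
------------
Channels are partitioned into ``k`` spatially contiguous clusters (k-means
on the electrode layout).  Each cluster ``c`` carries a phase process

    phi_c(t) = 2 pi f_c t + theta_c + sqrt(1 - b) * J * z_c(t)

and each channel adds private jitter

    phi_i(t) = phi_c(t) + sqrt(1 - w) * J * z_i(t),

where ``w``/``b`` are the within-/between-cluster coupling knobs in [0, 1],
``J`` is the jitter scale in radians and ``z`` are independent
mean-reverting (damped) random walks with unit stationary variance, so the
phase-jitter variance is scaled by ``(1 - coupling)`` but stays stationary:
the coupling -> correlation map does not drift with record length.  The
channel signal is ``a_i sin(phi_i)`` (log-normal per-channel amplitude)
plus Gaussian noise and an optional low-frequency drift (0.2 Hz sinusoid
plus linear ramp), giving the detrending step a realistic target.

``w = 1`` with zero noise and drift makes channels within a cluster exact
scalar multiples of each other (pairwise correlation 1); ``w = 0`` leaves
only the shared oscillation, heavily jittered.  All randomness derives from
the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .ensemble import Epoch, SignalEnsemble
from .errors import ParameterError
from .preprocess import WELCH_NPERSEG

#: Phase-jitter scale (radians): stationary SD of a fully uncoupled
#: channel's private phase jitter.
JITTER_RAD = 1.0
#: Mean-reversion time constant of the phase jitter, seconds.
JITTER_TAU_S = 0.5
#: Log-normal amplitude jitter (SD of log-amplitude).
AMP_JITTER_SD = 0.1
#: Respiratory-band drift frequency, Hz.
DRIFT_FREQ_HZ = 0.2


@dataclass
class ElectrodeLayout:
    """2-D electrode positions on the unit disc."""

    channel_ids: list[int]
    coordinates: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel ids must be unique")
        if self.coordinates.shape != (len(self.channel_ids), 2):
            raise ParameterError("coordinates must be (n_channels, 2)")
        r2 = (self.coordinates**2).sum(axis=1)
        if np.any(r2 > 1.0 + 1e-9):
            raise ParameterError("all electrodes must lie on the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)


@dataclass
class GroundTruth:
    """Generator-known structure for parameter-recovery tests."""

    cluster_label: np.ndarray
    coupling: np.ndarray
    df_hz: np.ndarray  # per cluster

    def __post_init__(self) -> None:
        self.cluster_label = np.asarray(self.cluster_label, dtype=int)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.df_hz = np.asarray(self.df_hz, dtype=float)
        if not np.allclose(self.coupling, self.coupling.T):
            raise ParameterError("coupling must be symmetric")
        if not np.allclose(np.diag(self.coupling), 1.0):
            raise ParameterError("coupling must have unit diagonal")


def generate_layout(n_channels: int, seed: int) -> ElectrodeLayout:
    """Quasi-uniform electrode layout on the unit disc.

    A sunflower (golden-angle) spiral gives even coverage; a small seeded
    jitter breaks its regularity.  Deterministic for a fixed seed.
    """
    if n_channels < 1:
        raise ParameterError("n_channels must be at least 1")
    rng = np.random.default_rng(seed)
    k = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt((k + 0.5) / n_channels) * 0.97
    theta = k * golden
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    xy += rng.normal(scale=0.015, size=xy.shape)
    radius = np.sqrt((xy**2).sum(axis=1))
    over = radius > 1.0
    if over.any():
        xy[over] /= radius[over, None] * (1.0 + 1e-9)
    return ElectrodeLayout(channel_ids=list(range(n_channels)), coordinates=xy)


def _ou_paths(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Unit-stationary-variance damped random walks, one per row."""
    from scipy.signal import lfilter

    alpha = np.exp(-1.0 / (JITTER_TAU_S * fs))
    innov_sd = np.sqrt(1.0 - alpha**2)
    n_paths, n_samples = shape
    z0 = rng.standard_normal(n_paths)
    eps = rng.standard_normal(shape) * innov_sd
    eps[:, 0] = z0  # stationary start
    z, _ = lfilter([1.0], [1.0, -alpha], eps, axis=1, zi=np.zeros((n_paths, 1)))
    return z


def generate_clustered_ensemble(
    layout: ElectrodeLayout,
    k_clusters: int,
    df_per_cluster: "list[float] | np.ndarray",
    within_coupling: float,
    between_coupling: float,
    noise_sd: float,
    drift_amplitude: float,
    duration_s: float,
    fs: float,
    seed: int,
    epoch_schedule: list[Epoch] | None = None,
) -> tuple[SignalEnsemble, GroundTruth]:
    """Generate a clustered oscillator ensemble with known ground truth.

    See the module docstring for the signal model.  Raises
    :class:`ParameterError` on couplings outside
    ``0 <= between <= within <= 1``, dominant frequencies outside
    ``(0, fs/2)``, or a record too short for one Welch spectral segment.
    """
    df = np.asarray(df_per_cluster, dtype=float)
    if df.size != k_clusters:
        raise ParameterError("df_per_cluster must supply one frequency per cluster")
    if not (0.0 <= between_coupling <= within_coupling <= 1.0):
        raise ParameterError(
            "couplings must satisfy 0 <= between_coupling <= within_coupling <= 1"
        )
    if np.any(df <= 0) or np.any(df >= fs / 2):
        raise ParameterError("dominant frequencies must lie in (0, fs/2)")
    if noise_sd < 0 or drift_amplitude < 0:
        raise ParameterError("noise_sd and drift_amplitude must be non-negative")
    n_samples = int(round(duration_s * fs))
    if n_samples < WELCH_NPERSEG:
        raise ParameterError(
            f"record of {n_samples} samples is shorter than one Welch segment "
            f"({WELCH_NPERSEG} samples)"
        )
    n_ch = layout.n_channels
    if k_clusters > n_ch:
        raise ParameterError("cannot have more clusters than channels")

    rng = np.random.default_rng(seed)
    if k_clusters == 1:
        labels = np.zeros(n_ch, dtype=int)
    else:
        km = KMeans(n_clusters=k_clusters, n_init=10, random_state=int(seed) % 2**31)
        raw = km.fit_predict(layout.coordinates)
        # relabel by first occurrence so labels are layout-stable
        remap: dict[int, int] = {}
        labels = np.empty(n_ch, dtype=int)
        for i, lab in enumerate(raw):
            if lab not in remap:
                remap[lab] = len(remap)
            labels[i] = remap[lab]

    t = np.arange(n_samples) / fs
    theta0 = rng.uniform(-np.pi, np.pi, size=k_clusters) * np.sqrt(
        1.0 - between_coupling
    )
    z_cluster = _ou_paths(rng, (k_clusters, n_samples), fs)
    z_channel = _ou_paths(rng, (n_ch, n_samples), fs)
    amp = np.exp(rng.normal(scale=AMP_JITTER_SD, size=n_ch))
    drift_phase = rng.uniform(-np.pi, np.pi, size=n_ch)
    noise = rng.normal(scale=noise_sd, size=(n_ch, n_samples)) if noise_sd > 0 else 0.0

    cluster_phase = (
        2.0 * np.pi * df[:, None] * t[None, :]
        + theta0[:, None]
        + np.sqrt(1.0 - between_coupling) * JITTER_RAD * z_cluster
    )
    phase = cluster_phase[labels] + np.sqrt(1.0 - within_coupling) * JITTER_RAD * z_channel
    data = amp[:, None] * np.sin(phase)
    if drift_amplitude > 0:
        drift = drift_amplitude * (
            np.sin(2.0 * np.pi * DRIFT_FREQ_HZ * t[None, :] + drift_phase[:, None])
            + t[None, :] / duration_s
        )
        data = data + drift
    data = data + noise

    coupling = np.where(
        labels[:, None] == labels[None, :], within_coupling, between_coupling
    ).astype(float)
    np.fill_diagonal(coupling, 1.0)
    truth = GroundTruth(cluster_label=labels, coupling=coupling, df_hz=df)
    ensemble = SignalEnsemble(
        data=data,
        fs=fs,
        channel_ids=list(layout.channel_ids),
        epoch_schedule=list(epoch_schedule) if epoch_schedule else [],
    )
    return ensemble, truth


def generate_noise_ensemble(
    n_channels: int, duration_s: float, fs: float, noise_sd: float, seed: int
) -> SignalEnsemble:
    """Independent Gaussian-noise channels (the fully disorganized control)."""
    if n_channels < 1:
        raise ParameterError("n_channels must be at least 1")
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    return SignalEnsemble(
        data=rng.normal(scale=noise_sd, size=(n_channels, n_samples)), fs=fs
    )
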