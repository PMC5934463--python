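"""On-disk ensemble bundle format.

A bundle is a plain-text pair sharing a stem:

- ``<stem>.csv`` — signals, rows = samples, columns = channels, header row
  of channel ids;
- ``<stem>.json`` — sidecar with ``schema_version``, ``fs``,
  ``channel_ids``, optional 2-D ``coordinates``, ``epoch_schedule`` and,
  for synthetic data, ``truth`` (cluster labels and per-cluster dominant
  frequencies).

The sidecar channel list must match the CSV columns; mismatches raise
:class:`~vforg.errors.SchemaError`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import SignalEnsemble
from .errors import SchemaError
from .synth import ElectrodeLayout, GroundTruth

SCHEMA_VERSION = 1


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in {".csv", ".json"} else p
    return stem.with_suffix(".csv"), stem.with_suffix(".json")


def write_ensemble(
    path: str | Path,
    ensemble: SignalEnsemble,
    layout: ElectrodeLayout | None = None,
    truth: GroundTruth | None = None,
) -> tuple[Path, Path]:
    """Write an ensemble bundle; returns the (csv, json) paths."""
    csv_path, json_path = _paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(ensemble.data.T, columns=[str(c) for c in ensemble.channel_ids])
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar: dict = {
        "schema_version": SCHEMA_VERSION,
        "fs": ensemble.fs,
        "channel_ids": list(ensemble.channel_ids),
        "epoch_schedule": [list(e) for e in ensemble.epoch_schedule],
    }
    if layout is not None:
        sidecar["coordinates"] = np.asarray(layout.coordinates).tolist()
    if truth is not None:
        sidecar["truth"] = {
            "cluster_label": truth.cluster_label.tolist(),
            "df_hz": truth.df_hz.tolist(),
        }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_ensemble(
    path: str | Path,
) -> tuple[SignalEnsemble, ElectrodeLayout | None, GroundTruth | None]:
    """Read an ensemble bundle written by :func:`write_ensemble`."""
    csv_path, json_path = _paths(path)
    if not json_path.exists():
        raise SchemaError(f"missing sidecar file {json_path}")
    if not csv_path.exists():
        raise SchemaError(f"missing signals file {csv_path}")
    sidecar = json.loads(json_path.read_text())
    for key in ("fs", "channel_ids"):
        if key not in sidecar:
            raise SchemaError(f"sidecar {json_path} lacks required key {key!r}")
    try:
        frame = pd.read_csv(csv_path, float_precision="round_trip")
    except ValueError as exc:
        raise SchemaError(f"unreadable signals file {csv_path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in frame.dtypes):
        raise SchemaError(f"non-numeric cells in {csv_path}")
    channel_ids = [int(c) for c in sidecar["channel_ids"]]
    if frame.shape[1] != len(channel_ids):
        raise SchemaError(
            f"sidecar lists {len(channel_ids)} channels but {csv_path} has "
            f"{frame.shape[1]} columns"
        )
    ensemble = SignalEnsemble(
        data=frame.to_numpy().T,
        fs=float(sidecar["fs"]),
        channel_ids=channel_ids,
        epoch_schedule=[tuple(e) for e in sidecar.get("epoch_schedule", [])],
    )
    layout = None
    if "coordinates" in sidecar:
        coords = np.asarray(sidecar["coordinates"], dtype=float)
        if coords.shape != (len(channel_ids), 2):
            raise SchemaError("coordinates shape does not match channel count")
        layout = ElectrodeLayout(channel_ids=channel_ids, coordinates=coords)
    truth = None
    if "truth" in sidecar:
        t = sidecar["truth"]
        labels = np.asarray(t["cluster_label"], dtype=int)
        if labels.size != len(channel_ids):
            raise SchemaError("truth labels length does not match channel count")
        df = np.asarray(t["df_hz"], dtype=float)
        coupling = np.eye(labels.size)  # pairwise coupling not serialized
        truth = GroundTruth(cluster_label=labels, coupling=coupling, df_hz=df)
    return ensemble, layout, truth


def read_count_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an externally supplied count series CSV with columns
    ``time_s, count`` (e.g. phase-singularity counts per recording)."""
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "time_s" not in cols or "count" not in cols:
        raise SchemaError(f"{path} must have columns time_s, count")
    return frame[cols["time_s"]].to_numpy(float), frame[cols["count"]].to_numpy(float)
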