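"""End-to-end orchestration: signals in, organization measures out.

``run_pipeline`` ties the stages together: load or simulate an ensemble,
detrend and screen channels, choose the lag window, sweep the four
organization measures (normalized Frobenius norm, density AUC, average
clustering AUC, cluster-count AUC) over sliding windows, fit epoch-knotted
trends, and optionally regress the cluster-count series against an external
complexity series.  All outputs are plain text (CSV/JSON); every file
carries the hash of the run manifest so reruns are verifiable.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from . import correlation as corr
from . import hclust, io, network, preprocess, synth, trends
from .ensemble import DEFAULT_VF_EPOCHS, SignalEnsemble
from .errors import ParameterError, VforgError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "input": {},          # {"bundle": path} or {}
    "synth": {},          # generate_clustered_ensemble kwargs (+ n_channels)
    "preprocess": {"detrend_segment_len": 1000, "select_channels": True},
    "lag": {"max_cycle_ms": None, "from_df": False},
    "window": {"len": trends.WINDOW_LEN, "hop": trends.WINDOW_HOP},
    "theta_grid": [0.0, 1.0, 0.05],   # start, stop, step
    "cutoff_grid": [0.0, 1.0, 0.05],
    "cut_height": 0.3,
    "measures": ["organization", "density_auc", "clustering_auc", "cluster_count_auc"],
    "compare": {},        # {"counts_csv": path, "granularity": "second"}
    "seed": 0,
    "out_dir": "vforg_results",
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _grid(spec) -> np.ndarray:
    if isinstance(spec, (list, tuple)) and len(spec) == 3:
        start, stop, step = spec
        grid = np.round(np.arange(start, stop + 1e-9, step), 10)
    else:
        grid = np.asarray(spec, dtype=float)
    if grid.size < 2:
        raise ParameterError("grids need at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("grids must be strictly increasing")
    return grid


def manifest_hash(config: dict) -> str:
    """Hash of every parameter that can influence the numbers (the output
    location is excluded so relocated reruns stay comparable)."""
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {tag}\n")
        frame.to_csv(fh, index=False)


def _load_input(config: dict):
    if config["input"].get("bundle"):
        ensemble, layout, truth = io.read_ensemble(config["input"]["bundle"])
        logger.info("loaded bundle %s", config["input"]["bundle"])
        return ensemble, layout, truth
    if not config["synth"]:
        raise ParameterError("config must provide input.bundle or synth parameters")
    params = dict(config["synth"])
    n_channels = params.pop("n_channels", 40)
    seed = params.pop("seed", config["seed"])
    layout = synth.generate_layout(n_channels, seed)
    if params.pop("default_epochs", False):
        params["epoch_schedule"] = list(DEFAULT_VF_EPOCHS)
    ensemble, truth = synth.generate_clustered_ensemble(layout, seed=seed, **params)
    return ensemble, layout, truth


def _lagspec(config: dict, ensemble: SignalEnsemble) -> corr.LagSpec:
    lag_cfg = config["lag"]
    if lag_cfg.get("max_cycle_ms"):
        return corr.lag_window_from_cycle_length(lag_cfg["max_cycle_ms"], ensemble.fs)
    if lag_cfg.get("from_df"):
        dfs = [
            preprocess.dominant_frequency(ch, ensemble.fs)
            for ch in ensemble.data
        ]
        cycle_ms = 1000.0 / float(np.mean(dfs))
        logger.info("mean DF %.2f Hz -> cycle %.1f ms", np.mean(dfs), cycle_ms)
        return corr.lag_window_from_cycle_length(cycle_ms, ensemble.fs)
    raise ParameterError("lag config must set max_cycle_ms or from_df")


def _measure_fn(name: str, theta_grid: np.ndarray, cutoff_grid: np.ndarray):
    if name == "organization":
        return corr.organization_measure
    if name == "density_auc":
        return lambda R: network.auc_over_thresholds(R, "density", theta_grid)
    if name == "clustering_auc":
        return lambda R: network.auc_over_thresholds(R, "avg_clustering", theta_grid)
    if name == "cluster_count_auc":
        return lambda R: hclust.cluster_count_curve(hclust.dissimilarity(R), cutoff_grid)[1]
    raise ParameterError(f"unknown measure {name!r}")


def run_pipeline(config: dict) -> Path:
    """Run the full analysis described by ``config``; returns the result
    directory.  Outputs are deterministic for a fixed config."""
    config = _merge(DEFAULT_CONFIG, config)
    theta_grid = _grid(config["theta_grid"])
    cutoff_grid = _grid(config["cutoff_grid"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = manifest_hash(config)

    stage = "input"
    try:
        ensemble, layout, truth = _load_input(config)

        stage = "preprocess"
        pp_cfg = config["preprocess"]
        ensemble = preprocess.detrend_piecewise_linear(
            ensemble, pp_cfg["detrend_segment_len"]
        )
        if pp_cfg.get("select_channels", True):
            mask = preprocess.select_channels(ensemble)
            (out_dir / "channel_mask.json").write_text(
                json.dumps(
                    {"manifest": tag, "channels": mask.to_records(ensemble.channel_ids)},
                    indent=1,
                )
            )
            if mask.n_kept < 2:
                raise ParameterError("fewer than 2 channels survive quality screening")
            kept_idx = np.nonzero(mask.keep)[0]
            ensemble = ensemble.subset(mask.keep)
            if layout is not None:
                layout = synth.ElectrodeLayout(
                    channel_ids=list(ensemble.channel_ids),
                    coordinates=layout.coordinates[kept_idx],
                )
            if truth is not None:
                truth = synth.GroundTruth(
                    cluster_label=truth.cluster_label[kept_idx],
                    coupling=truth.coupling[np.ix_(kept_idx, kept_idx)],
                    df_hz=truth.df_hz,
                )

        stage = "lag"
        lagspec = _lagspec(config, ensemble)

        stage = "full-record correlation"
        R_full = corr.correlation_matrix(ensemble, lagspec)
        r_frame = pd.DataFrame(
            R_full.R, columns=[str(c) for c in ensemble.channel_ids]
        )
        _write_csv(r_frame, out_dir / "correlation_full.csv", tag)

        stage = "hierarchical clustering"
        dend = hclust.average_linkage(hclust.dissimilarity(R_full))
        cmap = hclust.cluster_map(
            dend,
            config["cut_height"],
            None if layout is None else layout.coordinates,
        )
        _write_csv(cmap, out_dir / "cluster_map.csv", tag)

        stage = "windowed measures"
        fits: dict[str, trends.TrendFit] = {}
        series_frames = []
        for name in config["measures"]:
            fn = _measure_fn(name, theta_grid, cutoff_grid)
            series = trends.windowed_measure(
                ensemble, lagspec, fn,
                window_len=config["window"]["len"],
                hop=config["window"]["hop"],
                measure_name=name,
            )
            series_frames.append(
                pd.DataFrame(
                    {"measure": name, "t_center_s": series.t_center_s, "value": series.values}
                )
            )
            stage = f"trend fit ({name})"
            if len(series) >= 3:
                fits[name] = trends.fit_epoch_trend(series, ensemble.epoch_schedule)
            stage = "windowed measures"
        _write_csv(pd.concat(series_frames), out_dir / "windowed_measures.csv", tag)

        stage = "trend export"
        trend_doc = {"manifest": tag, "fits": {}}
        for name, fit in fits.items():
            trend_doc["fits"][name] = {
                "intercept": fit.intercept,
                "slope": fit.slope,
                "slope_changes": fit.slope_changes.tolist(),
                "knots_s": fit.knots_s.tolist(),
                "residual_sd": fit.residual_sd,
            }
        (out_dir / "trend_fits.json").write_text(json.dumps(trend_doc, indent=1))

        stage = "comparison"
        if config["compare"].get("counts_csv"):
            times, counts = io.read_count_series(config["compare"]["counts_csv"])
            cc = next(f for f in series_frames if f["measure"].iloc[0] == "cluster_count_auc")
            if config["compare"].get("granularity", "second") == "second":
                xt, xv = cmp.align_per_second(cc["t_center_s"].to_numpy(), cc["value"].to_numpy())
                common = np.intersect1d(np.floor(xt), np.floor(times))
                xv = xv[np.isin(np.floor(xt), common)]
                yv = counts[np.isin(np.floor(times), common)]
            else:
                m = min(len(cc), len(counts))
                xv, yv = cc["value"].to_numpy()[:m], counts[:m]
            r2 = cmp.rsquared(cmp.MeasurePair(x=xv, y=yv))
            (out_dir / "comparison.json").write_text(
                json.dumps({"manifest": tag, "rsquared": r2, "n_points": len(xv)}, indent=1)
            )

        stage = "manifest"
        (out_dir / "manifest.json").write_text(
            json.dumps({"manifest": tag, "config": config, "lag_d": lagspec.d,
                        "n_channels": ensemble.n_channels,
                        "n_samples": ensemble.n_samples}, indent=1, default=str)
        )
    except VforgError:
        logger.error("pipeline stage %r failed", stage)
        raise
    return out_dir
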