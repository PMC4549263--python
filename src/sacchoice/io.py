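"""File formats: tidy gaze CSV, an Eyelink-ASC-like dialect, YAML config.

The tidy gaze format is one CSV with columns
``subject, block, trial, t_ms, x_px, y_px`` (t_ms relative to stimulus
onset). The ASC-like dialect is one text file per trial with ``MSG``
lines marking trial start and stimulus onset and tab-separated sample
lines ``t x y`` using absolute timestamps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ScreenGeometry
from .synthetic import (
    ArtifactModel,
    ConditionParams,
    ConstantError,
    GazeTrace,
    LatencyDependentError,
    NoiseModel,
    ShiftedLogNormalLatency,
    SimulatedDataset,
    TruncatedNormalLatency,
)


def gaze_frame(dataset: SimulatedDataset) -> pd.DataFrame:
    """All traces of a dataset in the tidy gaze format."""
    parts = []
    for spec, trace in zip(dataset.design.trials, dataset.traces):
        parts.append(
            pd.DataFrame(
                {
                    "subject": spec.subject,
                    "block": spec.block,
                    "trial": spec.trial_index,
                    "t_ms": trace.t,
                    "x_px": trace.x,
                    "y_px": trace.y,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_dataset(dataset: SimulatedDataset, out_dir, asc: bool = False) -> dict[str, Path]:
    """Write gaze, trial-table and ground-truth CSVs; returns the paths.

    With ``asc=True`` an ``asc/`` directory with one ASC-like text file
    per trial (``<subject>_<trial>.asc``) is written as well.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gaze": out / "gaze.csv",
        "trials": out / "trials.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    gaze_frame(dataset).to_csv(paths["gaze"], index=False)
    dataset.design.to_frame().to_csv(paths["trials"], index=False)
    dataset.truth_frame().to_csv(paths["ground_truth"], index=False)
    if asc:
        asc_dir = out / "asc"
        asc_dir.mkdir(exist_ok=True)
        for spec, trace in zip(dataset.design.trials, dataset.traces):
            write_asc(trace, asc_dir / f"{spec.subject}_{spec.trial_index}.asc",
                      trial_id=spec.trial_index)
        paths["asc"] = asc_dir
    return paths


def read_gaze(path) -> dict[tuple[str, int], GazeTrace]:
    """Read gaze traces from a tidy CSV or a directory of ASC files."""
    path = Path(path)
    if path.is_dir():
        traces = {}
        for f in sorted(path.glob("*.asc")):
            subject, trial = f.stem.rsplit("_", 1)
            traces[(subject, int(trial))] = read_asc(f)
        if not traces:
            raise ValueError(f"{path}: no .asc files found")
        return traces
    return read_gaze_csv(path)


def read_gaze_csv(path) -> dict[tuple[str, int], GazeTrace]:
    """Read a tidy gaze CSV into per-trial traces keyed by (subject, trial)."""
    df = pd.read_csv(path)
    traces = {}
    for (subject, trial), g in df.groupby(["subject", "trial"], sort=False):
        traces[(str(subject), int(trial))] = GazeTrace(
            t=g["t_ms"].to_numpy(), x=g["x_px"].to_numpy(), y=g["y_px"].to_numpy()
        )
    return traces


# ---------------------------------------------------------------------------
# ASC-like dialect

_ASC_OFFSET = 10_000  # arbitrary absolute clock origin per trial


def write_asc(trace: GazeTrace, path, trial_id: int = 1) -> None:
    """Write one trial as ASC-like text (MSG lines + tab-separated samples)."""
    t0 = _ASC_OFFSET - int(trace.t[0])
    lines = [f"MSG\t{t0 + int(trace.t[0])} TRIALID {trial_id}",
             f"MSG\t{t0 + trace.stimulus_onset} STIMONSET"]
    for ti, xi, yi in zip(trace.t, trace.x, trace.y):
        lines.append(f"{t0 + int(ti)}\t{xi:.2f}\t{yi:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_asc(path) -> GazeTrace:
    """Parse the ASC-like dialect back into a GazeTrace.

    Sample timestamps are re-expressed relative to the STIMONSET message.
    """
    onset_abs = None
    t, x, y = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("MSG"):
            parts = line.split()
            if parts[-1] == "STIMONSET":
                onset_abs = int(parts[1])
            continue
        parts = line.split()
        t.append(int(parts[0]))
        x.append(float(parts[1]))
        y.append(float(parts[2]))
    if onset_abs is None:
        raise ValueError(f"{path}: no STIMONSET message")
    return GazeTrace(t=np.asarray(t) - onset_abs, x=np.asarray(x), y=np.asarray(y))


# ---------------------------------------------------------------------------
# YAML simulation config

_LATENCY_MODELS = {
    "shifted_lognormal": ShiftedLogNormalLatency,
    "truncated_normal": TruncatedNormalLatency,
}
_ERROR_MODELS = {
    "constant": ConstantError,
    "latency_dependent": LatencyDependentError,
}


def load_params_yaml(path):
    """Load simulation parameters from YAML.

    Layout::

        noise: {jitter_sd_deg: 0.15, measurement_sd_px: 0.0}
        artifacts: {p_anticipation: 0.03, p_fixation_break: 0.03}
        conditions:
          "FamiliarFace|Object":
            latency: {model: shifted_lognormal, mean_ms: 172}
            error: {model: constant, p_error: 0.073}

    Returns ``(condition_params, noise_model, artifact_model)``; any
    missing section falls back to its default.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    noise = NoiseModel(**cfg.get("noise", {}))
    artifacts = ArtifactModel(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in cfg.get("artifacts", {}).items()})
    conditions = None
    if "conditions" in cfg:
        conditions = {}
        for key, spec in cfg["conditions"].items():
            task = tuple(key.split("|"))
            lat_cfg = dict(spec["latency"])
            err_cfg = dict(spec["error"])
            lat_cls = _LATENCY_MODELS[lat_cfg.pop("model")]
            err_cls = _ERROR_MODELS[err_cfg.pop("model")]
            conditions[task] = ConditionParams(
                latency_model=lat_cls(**lat_cfg), error_model=err_cls(**err_cfg)
            )
    return conditions, noise, artifacts
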