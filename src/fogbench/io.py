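"""File formats: recording CSV dialect, DAPHNET text loader, window-set
bundles, model checkpoints, run manifests and strict YAML configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fogbench.cohort import RegimeSpec, SensorRecording
from fogbench.preprocessing import WindowSet
from fogbench.tcn import TCN, TCNSpec, build_model

__all__ = [
    "write_recording",
    "read_recording",
    "read_daphnet",
    "write_cohort",
    "read_cohort",
    "save_windowset",
    "load_windowset",
    "save_checkpoint",
    "load_checkpoint",
    "load_regime_config",
    "write_manifest",
]

_TIME_TOL = 1e-6

# DAPHNET column layout: ms timestamp, ankle (3), thigh (3), trunk (3),
# annotation. Annotation 0 = outside experiment (dropped), 1 = no freeze,
# 2 = freeze.
_DAPHNET_COLUMNS = 11
_DAPHNET_ANKLE_THIGH = slice(1, 7)


def write_recording(recording: SensorRecording, path: str | Path) -> Path:
    """Write the CSV dialect: time_s, one column per channel, label."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    df = pd.DataFrame({"time_s": t})
    for i, name in enumerate(recording.channel_names):
        df[name] = recording.signal[:, i]
    df["label"] = recording.labels
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_recording(path: str | Path) -> SensorRecording:
    """Read the CSV dialect back; the sample rate is inferred and validated."""
    path = Path(path)
    df = pd.read_csv(path)
    for required in ("time_s", "label"):
        if required not in df.columns:
            raise ValueError(f"{path.name}: missing required column {required!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: need at least two samples to infer the rate")
    steps = np.diff(t)
    step = steps.mean()
    if step <= 0 or np.abs(steps - step).max() > _TIME_TOL:
        raise ValueError(f"{path.name}: time_s is not a constant sampling grid")
    channels = [c for c in df.columns if c not in ("time_s", "label")]
    return SensorRecording(
        subject_id=path.stem,
        sample_rate_hz=int(round(1.0 / step)),
        signal=df[channels].to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
        channel_names=tuple(channels),
    )


def read_daphnet(path: str | Path) -> SensorRecording:
    """Load a DAPHNET-format text file (optional real-data path).

    Whitespace-separated rows: millisecond timestamp, nine acceleration
    columns (ankle, thigh, trunk triaxial), and an annotation in {0, 1, 2}.
    Rows annotated 0 (outside the experiment) are dropped; 2 maps to freeze
    (label 1) and 1 to no-freeze (label 0). Only the ankle and thigh
    channels (first six signal columns) are retained.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != _DAPHNET_COLUMNS:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {_DAPHNET_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed numeric value"
                ) from None
    data = np.asarray(rows)
    ann = data[:, -1].astype(int)
    if not np.isin(ann, (0, 1, 2)).all():
        raise ValueError(f"{path.name}: annotations must be in {{0, 1, 2}}")
    keep = ann != 0
    data = data[keep]
    if data.shape[0] < 2:
        raise ValueError(f"{path.name}: too few in-experiment rows")
    step_ms = float(np.median(np.diff(data[:, 0])))
    return SensorRecording(
        subject_id=path.stem,
        sample_rate_hz=int(round(1000.0 / step_ms)),
        signal=data[:, _DAPHNET_ANKLE_THIGH],
        labels=(data[:, -1].astype(int) == 2).astype(np.int8),
        channel_names=(
            "ankle_x", "ankle_y", "ankle_z", "thigh_x", "thigh_y", "thigh_z",
        ),
    )


def write_cohort(cohort: list[SensorRecording], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [write_recording(rec, outdir / f"{rec.subject_id}.csv") for rec in cohort]


def read_cohort(indir: str | Path) -> list[SensorRecording]:
    paths = sorted(Path(indir).glob("*.csv"))
    if not paths:
        raise ValueError(f"no recording CSVs found in {indir}")
    return [read_recording(p) for p in paths]


def save_windowset(ws: WindowSet, path: str | Path) -> Path:
    """Compressed array bundle plus a JSON sidecar describing shapes."""
    path = Path(path)
    np.savez_compressed(
        path,
        windows=ws.windows,
        labels=ws.labels,
        subject_ids=ws.subject_ids.astype(str),
    )
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "n_windows": int(ws.n_windows),
        "window_s": ws.window_s,
        "overlap_frac": ws.overlap_frac,
        "sample_rate_hz": ws.sample_rate_hz,
        "n_channels": int(ws.n_channels),
        "prevalence": ws.prevalence,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_windowset(path: str | Path) -> WindowSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path, allow_pickle=False) as npz:
        return WindowSet(
            windows=npz["windows"],
            labels=npz["labels"],
            subject_ids=npz["subject_ids"].astype(object),
            window_s=sidecar["window_s"],
            overlap_frac=sidecar["overlap_frac"],
            sample_rate_hz=sidecar["sample_rate_hz"],
        )


def save_checkpoint(model: TCN, path: str | Path) -> Path:
    """Self-describing checkpoint: weights plus the embedded spec JSON."""
    path = Path(path)
    state = model.state_dict()
    arrays = {f"param_{i}": v for i, v in enumerate(state["params"])}
    for i, (m, v) in enumerate(state["bn"]):
        arrays[f"bn_mean_{i}"] = m
        arrays[f"bn_var_{i}"] = v
    np.savez_compressed(path, spec=np.array(model.spec.to_json()), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> TCN:
    with np.load(path, allow_pickle=False) as npz:
        spec = TCNSpec.from_json(str(npz["spec"]))
        model = build_model(spec)
        n_params = len([k for k in npz.files if k.startswith("param_")])
        n_bn = len([k for k in npz.files if k.startswith("bn_mean_")])
        state = {
            "params": [npz[f"param_{i}"] for i in range(n_params)],
            "bn": [(npz[f"bn_mean_{i}"], npz[f"bn_var_{i}"]) for i in range(n_bn)],
        }
    model.load_state_dict(state)
    return model


def load_regime_config(path: str | Path) -> RegimeSpec:
    """Strict YAML -> RegimeSpec; unknown keys are fatal."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: regime config must be a mapping")
    known = {f.name for f in fields(RegimeSpec)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("gait_band_hz", "freeze_band_hz", "episode_duration_s"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RegimeSpec(**raw)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    outdir: str | Path, config: dict, seed: int, artifacts: list[str]
) -> Path:
    """Reproducibility manifest: config hash, seed, versions, artifact files."""
    import fogbench

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {"fogbench": fogbench.__version__, "numpy": np.__version__},
        "artifacts": sorted(artifacts),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
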