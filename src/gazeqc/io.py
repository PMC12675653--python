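"""Plain-text I/O: session CSVs, ground-truth JSON, camera/screen YAML, PNG frames."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .mapping import CameraModel, ScreenGeometry
from .recording import CSV_COLUMNS, GazeRecording
from .synthetic import GroundTruth


def recording_filename(rec: GazeRecording) -> str:
    return f"trial{rec.trial_index}_{rec.condition}_{rec.phase}.csv"


def write_recording(rec: GazeRecording, path) -> None:
    rec.to_frame()[CSV_COLUMNS].to_csv(path, index=False)


def read_recording(path, space: str = "degrees") -> GazeRecording:
    return GazeRecording.from_frame(pd.read_csv(path), space=space)


def write_session(out_dir, recordings, truth: GroundTruth | None = None,
                  manifest: dict | None = None) -> Path:
    """One CSV per trial phase, ground truth JSON sidecar, YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out / recording_filename(rec))
    if truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(truth.to_jsonable(), indent=2))
    if manifest is not None:
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_session(session_dir, space: str = "degrees") -> list:
    """All trial-phase CSVs of a session directory, in (trial, time) order."""
    paths = sorted(Path(session_dir).glob("trial*_*.csv"))
    recs = [read_recording(p, space=space) for p in paths]
    recs.sort(key=lambda r: r.timestamps[0] if r.n else 0.0)
    return recs


def write_frame(image: np.ndarray, path) -> None:
    iio.imwrite(Path(path), image)


def read_frame(path) -> np.ndarray:
    return iio.imread(Path(path))


def load_camera(path) -> CameraModel:
    cfg = yaml.safe_load(Path(path).read_text())
    return CameraModel(
        fx=cfg["fx"], fy=cfg["fy"], cx=cfg["cx"], cy=cfg["cy"],
        distortion=tuple(cfg.get("distortion", [0, 0, 0, 0, 0])),
        width=cfg.get("width", 1280), height=cfg.get("height", 720),
    )


def save_camera(camera: CameraModel, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "fx": camera.fx, "fy": camera.fy, "cx": camera.cx, "cy": camera.cy,
        "distortion": list(camera.distortion),
        "width": camera.width, "height": camera.height,
    }))


def load_screen(path) -> ScreenGeometry:
    cfg = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(ScreenGeometry)}
    return ScreenGeometry(**{k: v for k, v in cfg.items() if k in fields})


def save_screen(screen: ScreenGeometry, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(screen)))
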