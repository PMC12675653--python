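"""Gaze sample containers shared by the generator, preprocessing and metrics stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PIXELS = "pixels"
DEGREES = "degrees"

#: column order used by every CSV this package reads or writes
CSV_COLUMNS = ["timestamp_s", "x", "y", "valid", "pupil", "condition", "phase", "trial"]


@dataclass
class GazeRecording:
    """Time series of gaze samples for one trial phase.

    Coordinates are either scene/screen pixels or screen-centered degrees of
    visual angle; the ``space`` tag makes the frame explicit.  Samples flagged
    invalid always carry NaN coordinates (enforced at construction).
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    pupil: np.ndarray
    space: str = DEGREES
    condition: str = "bright"
    phase: str = "measurement"
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float).copy()
        self.y = np.asarray(self.y, dtype=float).copy()
        self.valid = np.asarray(self.valid, dtype=bool)
        self.pupil = np.asarray(self.pupil, dtype=float)
        n = len(self.timestamps)
        for name in ("x", "y", "valid", "pupil"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"channel {name!r} length mismatch")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if self.space not in (PIXELS, DEGREES):
            raise ConfigurationError(f"unknown coordinate space {self.space!r}")
        # invalid => NaN coordinates
        self.x[~self.valid] = np.nan
        self.y[~self.valid] = np.nan

    @property
    def n(self) -> int:
        return len(self.timestamps)

    @property
    def valid_mask(self) -> np.ndarray:
        """Samples that are flagged valid and carry finite coordinates."""
        return self.valid & np.isfinite(self.x) & np.isfinite(self.y)

    def take(self, index: np.ndarray) -> "GazeRecording":
        """New recording restricted to ``index`` (bool mask or integer index)."""
        return replace(
            self,
            timestamps=self.timestamps[index],
            x=self.x[index],
            y=self.y[index],
            valid=self.valid[index],
            pupil=self.pupil[index],
        )

    def with_coords(self, x: np.ndarray, y: np.ndarray, space: str) -> "GazeRecording":
        """Same samples re-expressed in another coordinate frame."""
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float), space=space)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps,
                "x": self.x,
                "y": self.y,
                "valid": self.valid.astype(int),
                "pupil": self.pupil,
                "condition": self.condition,
                "phase": self.phase,
                "trial": self.trial_index,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, space: str = DEGREES) -> "GazeRecording":
        if len(df) == 0:
            raise ConfigurationError("empty table")
        condition = str(df["condition"].iloc[0]) if "condition" in df else "bright"
        phase = str(df["phase"].iloc[0]) if "phase" in df else "measurement"
        trial = int(df["trial"].iloc[0]) if "trial" in df else 0
        return cls(
            timestamps=df["timestamp_s"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            valid=df["valid"].to_numpy().astype(bool),
            pupil=df["pupil"].to_numpy(float) if "pupil" in df else np.full(len(df), np.nan),
            space=space,
            condition=condition,
            phase=phase,
            trial_index=trial,
        )
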