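"""Data-cleaning chain: trial trimming, distance filter, SD outlier filter.

Stage order matches the analysis convention: invalid samples already carry
NaN, then the middle 75% of the measurement window is kept, then a 10-degree
distance filter removes blink artifacts, then a single-pass 3-SD filter
removes remaining outliers.  NaN samples are exempt from both filter stages:
they count toward data loss, which is defined before cleaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyTrial, InsufficientData
from .recording import GazeRecording


@dataclass
class FilterReport:
    """Bookkeeping of one cleaning pass."""

    n_input: int = 0
    n_removed_distance: int = 0
    n_removed_sd: int = 0
    n_invalid: int = 0
    fraction_removed: float = 0.0

    def __post_init__(self):
        if min(self.n_input, self.n_removed_distance, self.n_removed_sd,
               self.n_invalid) < 0:
            raise DomainError("report counts must be non-negative")
        if self.n_removed_distance + self.n_removed_sd > self.n_input - self.n_invalid:
            raise DomainError("removed more samples than were valid")


@dataclass(frozen=True)
class PupilCalibration:
    """Artificial-pupil reference for converting device pupil-area units to mm."""

    d_artificial: float            # mm
    d_artificial_recorded: float   # device area units

    def __post_init__(self):
        if self.d_artificial <= 0 or self.d_artificial_recorded <= 0:
            raise DomainError("calibration values must be strictly positive")


@dataclass(frozen=True)
class CleaningConfig:
    trim_fraction: float = 0.125
    distance_radius: float = 10.0
    sd_multiplier: float = 3.0
    sd_iterate: bool = False


def trim_trial(rec: GazeRecording, fraction: float = 0.125) -> GazeRecording:
    """Drop the initial and final ``fraction`` of samples (by count, floored)."""
    n = rec.n
    if n == 0:
        raise EmptyTrial("cannot trim an empty recording")
    k = math.floor(fraction * n)
    return rec.take(np.arange(k, n - k))


def distance_filter(rec: GazeRecording, target=(0.0, 0.0),
                    radius: float = 10.0):
    """Remove valid samples strictly more than ``radius`` degrees from the target.

    NaN samples pass through unremoved; they are data loss, not outliers.
    Returns (filtered recording, FilterReport).
    """
    tx, ty = float(target[0]), float(target[1])
    vm = rec.valid_mask
    d = np.hypot(rec.x - tx, rec.y - ty)
    remove = vm & (d > radius)
    out = rec.take(~remove)
    report = FilterReport(
        n_input=rec.n,
        n_removed_distance=int(remove.sum()),
        n_invalid=int((~vm).sum()),
        fraction_removed=_safe_fraction(int(remove.sum()), rec.n - int((~vm).sum())),
    )
    return out, report


def sd_outlier_filter(rec: GazeRecording, k: float = 3.0, iterate: bool = False):
    """Single-pass removal of valid samples beyond k standard deviations.

    Mean and SD (population denominator) are computed per axis over valid
    samples; a sample is removed when it exceeds the bound on either axis.
    A zero-SD axis removes nothing.  ``iterate`` repeats the pass until no
    sample is removed (off by default).
    """
    vm = rec.valid_mask
    if int(vm.sum()) < 2:
        raise InsufficientData("SD filter needs at least 2 valid samples")
    total_removed = 0
    n_input = rec.n
    n_invalid = int((~vm).sum())
    current = rec
    while True:
        vm = current.valid_mask
        remove = np.zeros(current.n, dtype=bool)
        for coords in (current.x, current.y):
            mu = float(np.mean(coords[vm]))
            sigma = float(np.std(coords[vm]))  # population form
            if sigma > 0:
                remove |= vm & (np.abs(coords - mu) > k * sigma)
        n_rm = int(remove.sum())
        total_removed += n_rm
        current = current.take(~remove)
        if not iterate or n_rm == 0:
            break
        if int(current.valid_mask.sum()) < 2:
            break
    report = FilterReport(
        n_input=n_input,
        n_removed_sd=total_removed,
        n_invalid=n_invalid,
        fraction_removed=_safe_fraction(total_removed, n_input - n_invalid),
    )
    return current, report


def pupil_area_to_mm(area, cal: PupilCalibration):
    """Device pupil-area units -> diameter in mm (square-root scaling).

    d_mm = d_artificial * sqrt(area / d_artificial_recorded).  NaN propagates.
    """
    arr = np.asarray(area, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise DomainError("pupil area must be non-negative")
    out = cal.d_artificial * np.sqrt(arr / cal.d_artificial_recorded)
    return out if arr.ndim else float(out)


def clean_pipeline(rec: GazeRecording, target=(0.0, 0.0),
                   config: CleaningConfig | None = None):
    """Full cleaning chain: trim -> distance filter -> SD filter.

    Degenerate inputs pass through: when fewer than 2 valid samples survive
    to the SD stage, that stage is skipped (an all-NaN trial yields an
    all-NaN output and a report, never an exception).  Note the SD stage is
    single-pass, so re-running the pipeline on its own output may remove a
    few further samples.

    Returns (cleaned recording, aggregated FilterReport).
    """
    config = config or CleaningConfig()
    trimmed = trim_trial(rec, config.trim_fraction)
    n_input = trimmed.n
    n_invalid = int((~trimmed.valid_mask).sum())
    filtered, rep_d = distance_filter(trimmed, target, config.distance_radius)
    if int(filtered.valid_mask.sum()) >= 2:
        cleaned, rep_s = sd_outlier_filter(filtered, config.sd_multiplier,
                                           iterate=config.sd_iterate)
        n_sd = rep_s.n_removed_sd
    else:
        cleaned, n_sd = filtered, 0
    report = FilterReport(
        n_input=n_input,
        n_removed_distance=rep_d.n_removed_distance,
        n_removed_sd=n_sd,
        n_invalid=n_invalid,
        fraction_removed=_safe_fraction(rep_d.n_removed_distance + n_sd,
                                        n_input - n_invalid),
    )
    return cleaned, report


def _safe_fraction(numerator: int, denominator: int) -> float:
    return numerator / denominator if denominator > 0 else 0.0
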