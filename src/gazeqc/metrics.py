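"""Data-quality metrics: accuracy, apparent gaze shift, STD, RMS-S2S, data loss.

All metrics operate on recordings in degree space.  Accuracy, STD and
RMS-S2S are computed on cleaned recordings; data loss is defined on the
un-cleaned trial recording.  Valid samples are those flagged valid with
finite coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyTrial, InsufficientData
from .recording import GazeRecording


@dataclass
class TrialMetrics:
    """Per-trial, per-condition quality values."""

    accuracy: float
    std: float
    rms_s2s: float
    data_loss: float
    n_valid: int
    condition: str
    trial_index: int


@dataclass
class ShiftResult:
    """Apparent gaze shift over sequential bright-dark trial pairs."""

    per_trial_shift: list
    mean_shift: float
    n_pairs: int


def accuracy(rec: GazeRecording, target=(0.0, 0.0)) -> float:
    """Mean Euclidean offset of valid samples from the target (degrees).

    This is the mean of distances, not the distance of the mean.
    """
    vm = rec.valid_mask
    if not vm.any():
        raise InsufficientData("accuracy needs at least one valid sample")
    d = np.hypot(rec.x[vm] - target[0], rec.y[vm] - target[1])
    return float(np.mean(d))


def apparent_gaze_shift(pairs) -> ShiftResult:
    """Mean distance between bright and dark gaze centroids over trial pairs.

    ``pairs`` is a sequence of (bright, dark) recordings from the same trial
    (sequential pairing sidesteps slow drift such as device slippage).
    """
    shifts = []
    for i, (bright, dark) in enumerate(pairs):
        bm, dm = bright.valid_mask, dark.valid_mask
        if not bm.any() or not dm.any():
            raise InsufficientData(f"pair {i} has an empty phase")
        bx, by = np.mean(bright.x[bm]), np.mean(bright.y[bm])
        dx, dy = np.mean(dark.x[dm]), np.mean(dark.y[dm])
        shifts.append(float(np.hypot(bx - dx, by - dy)))
    if not shifts:
        raise InsufficientData("no trial pairs supplied")
    return ShiftResult(per_trial_shift=shifts, mean_shift=float(np.mean(shifts)),
                       n_pairs=len(shifts))


def std_precision(rec: GazeRecording) -> float:
    """Overall dispersion: sqrt of mean squared Euclidean deviation from the centroid.

    Population denominator (N); equals sqrt(var_x + var_y) in population form.
    """
    vm = rec.valid_mask
    if not vm.any():
        raise InsufficientData("STD needs at least one valid sample")
    x, y = rec.x[vm], rec.y[vm]
    return float(np.sqrt(np.mean((x - x.mean()) ** 2 + (y - y.mean()) ** 2)))


def rms_s2s(rec: GazeRecording) -> float:
    """RMS of Euclidean displacements between consecutive valid samples.

    Only index-consecutive pairs with both members valid are used; pairs that
    span a NaN gap are excluded and the denominator is the number of usable
    pairs (reduces to N-1 on gap-free data).
    """
    vm = rec.valid_mask
    if rec.n < 2:
        raise InsufficientData("RMS-S2S needs at least 2 samples")
    pair = vm[:-1] & vm[1:]
    if not pair.any():
        raise InsufficientData("no consecutive valid sample pairs")
    dx = np.diff(rec.x)[pair]
    dy = np.diff(rec.y)[pair]
    return float(np.sqrt(np.mean(dx * dx + dy * dy)))


def data_loss(rec: GazeRecording) -> float:
    """Percentage of invalid samples in the un-cleaned trial recording."""
    if rec.n == 0:
        raise EmptyTrial("data loss undefined for an empty trial")
    return float(100.0 * (~rec.valid_mask).sum() / rec.n)


def compute_trial_metrics(cleaned: GazeRecording, raw: GazeRecording,
                          target=(0.0, 0.0)) -> TrialMetrics:
    """Bundle the four per-recording metrics for one trial condition."""
    return TrialMetrics(
        accuracy=accuracy(cleaned, target),
        std=std_precision(cleaned),
        rms_s2s=rms_s2s(cleaned),
        data_loss=data_loss(raw),
        n_valid=int(cleaned.valid_mask.sum()),
        condition=cleaned.condition,
        trial_index=cleaned.trial_index,
    )
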