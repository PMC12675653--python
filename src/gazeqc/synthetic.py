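"""Ground-truth-known session simulator.

Generates bright/dark fixation sessions with the structure the analysis
stages assume: per trial a bright period then a dark period, each split into
an adaptation and a measurement phase; an injected apparent gaze shift in the
dark condition; AR(1) gaze noise with independently controllable dispersion
and sample-to-sample jitter; Poisson blinks that invalidate samples (and,
optionally, large entry/exit excursions for the distance filter to catch);
and a pupil trace that settles near distinct bright/dark diameters.

Everything is deterministic given (inputs, seed) and every injected quantity
is recorded in a :class:`GroundTruth` sidecar that the pipeline never reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError
from .mapping import CameraModel, ScreenGeometry
from .recording import DEGREES, GazeRecording

NAN_ONLY = "nan_only"
NAN_PLUS_EXCURSION = "nan_plus_excursion"

EXCURSION_AMPLITUDE_DEG = 15.0
EXCURSION_SAMPLES = 2  # samples on each side of a blink gap


# --------------------------------------------------------------------------- profiles


@dataclass(frozen=True)
class DeviceProfile:
    """Stochastic signal characteristics of a simulated eye tracker."""

    name: str = "sim-100"
    sampling_rate: float = 100.0
    noise_std: float = 0.3          # degrees, stationary isotropic dispersion
    s2s_noise: float | None = None  # degrees, RMS sample-to-sample target; None -> white
    blink_rate: float = 0.1         # events / s
    blink_duration: float = 0.15    # s
    data_loss_mode: str = NAN_ONLY

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.noise_std < 0:
            raise ConfigurationError("noise_std must be non-negative")
        if self.blink_rate < 0 or self.blink_duration < 0:
            raise ConfigurationError("blink parameters must be non-negative")
        if self.data_loss_mode not in (NAN_ONLY, NAN_PLUS_EXCURSION):
            raise ConfigurationError(f"unknown data_loss_mode {self.data_loss_mode!r}")

    @property
    def ar_coefficient(self) -> float:
        """AR(1) coefficient that realizes the requested sample-to-sample jitter.

        For a stationary isotropic AR(1) process with per-axis SD sigma, the
        two-dimensional RMS of consecutive displacements is
        2*sigma*sqrt(1 - rho), so rho = 1 - (s2s / (2*sigma))**2.
        """
        if self.noise_std == 0:
            return 0.0
        if self.s2s_noise is None:
            return 0.0  # white noise: s2s = 2*sigma
        rho = 1.0 - (self.s2s_noise / (2.0 * self.noise_std)) ** 2
        return float(np.clip(rho, 0.0, 0.9999))


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant ground truth: artifact shift, calibration bias, pupil sizes."""

    psa_shift: tuple = (2.0, 0.0)   # degrees, added in the dark condition
    bias_bright: tuple = (0.0, 0.0)  # degrees, present in both conditions
    pupil_bright: float = 2.88       # mm
    pupil_dark: float = 5.05         # mm

    def __post_init__(self):
        if self.pupil_bright <= 0 or self.pupil_dark <= 0:
            raise ConfigurationError("pupil diameters must be positive")


@dataclass(frozen=True)
class TrialSchedule:
    """Trial timing: each period is adaptation then measurement."""

    n_trials: int = 3
    bright_duration: float = 10.0
    dark_duration: float = 10.0
    adaptation_duration: float = 5.0
    measurement_duration: float = 5.0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ConfigurationError("n_trials must be positive")
        for name in ("bright_duration", "dark_duration", "adaptation_duration",
                     "measurement_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        total = self.adaptation_duration + self.measurement_duration
        if not (math.isclose(total, self.bright_duration)
                and math.isclose(total, self.dark_duration)):
            raise ConfigurationError(
                "adaptation + measurement must equal both period durations"
            )


@dataclass
class GroundTruth:
    """Injected parameters of a generated session; consumed only by tests."""

    true_gaze_angle: dict                 # condition -> (x, y) degrees
    injected_shift: tuple                 # degrees
    injected_loss_fraction: float         # realized NaN fraction over the session
    n_total: int = 0
    n_invalid_by_phase: dict = field(default_factory=dict)
    n_excursion_by_phase: dict = field(default_factory=dict)
    marker_pixel_positions: dict | None = None
    true_distance: float | None = None

    def phase_key(self, trial: int, condition: str, phase: str) -> tuple:
        return (trial, condition, phase)

    def to_jsonable(self) -> dict:
        return {
            "true_gaze_angle": {k: list(v) for k, v in self.true_gaze_angle.items()},
            "injected_shift": list(self.injected_shift),
            "injected_loss_fraction": self.injected_loss_fraction,
            "n_total": self.n_total,
            "n_invalid_by_phase": {
                "|".join(map(str, k)): v for k, v in self.n_invalid_by_phase.items()
            },
            "n_excursion_by_phase": {
                "|".join(map(str, k)): v for k, v in self.n_excursion_by_phase.items()
            },
            "true_distance": self.true_distance,
        }


def random_participant(rng: np.random.Generator, *, shift_magnitude: float | None = None,
                       bias_std: float = 0.3) -> ParticipantProfile:
    """Draw a participant with artifact magnitude spanning roughly 0.9-3.5 deg.

    The shift direction is uniform on the circle (a modeling choice: only
    magnitudes are constrained by observation).
    """
    if shift_magnitude is None:
        shift_magnitude = float(rng.uniform(0.9, 3.5))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    shift = (shift_magnitude * np.cos(theta), shift_magnitude * np.sin(theta))
    bias = tuple(rng.normal(0.0, bias_std, size=2))
    pb = float(rng.normal(2.88, 0.25))
    pd_ = float(rng.normal(5.05, 0.35))
    pd_ = max(pd_, pb + 0.5)  # dark pupil always larger in default generation
    return ParticipantProfile(psa_shift=shift, bias_bright=bias,
                              pupil_bright=max(pb, 1.0), pupil_dark=pd_)


# --------------------------------------------------------------------------- gaze


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with SD ``sigma`` and coefficient ``rho``."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    if rho == 0:
        return rng.normal(0.0, sigma, size=n)
    from scipy.signal import lfilter

    w = rng.normal(0.0, sigma * math.sqrt(1.0 - rho * rho), size=n)
    w[0] = rng.normal(0.0, sigma)
    out, _ = lfilter([1.0], [1.0, -rho], w, zi=[0.0])
    return out


def _inject_blinks(rng: np.random.Generator, n: int, device: DeviceProfile,
                   duration: float):
    """Blink NaN mask and excursion offsets for one phase.

    Returns (nan_mask, excursion_offsets (n,2)); excursion offsets are zero
    outside blink shoulders.  NaN always wins over an excursion.
    """
    nan_mask = np.zeros(n, dtype=bool)
    exc = np.zeros((n, 2))
    if device.blink_rate <= 0 or device.blink_duration <= 0 or n == 0:
        return nan_mask, exc
    n_events = rng.poisson(device.blink_rate * duration)
    gap = max(int(round(device.blink_duration * device.sampling_rate)), 1)
    for _ in range(n_events):
        onset = int(rng.integers(0, n))
        end = min(onset + gap, n)
        nan_mask[onset:end] = True
        if device.data_loss_mode == NAN_PLUS_EXCURSION:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            offset = EXCURSION_AMPLITUDE_DEG * np.array([np.cos(theta), np.sin(theta)])
            for i in range(max(onset - EXCURSION_SAMPLES, 0), onset):
                exc[i] = offset
            for i in range(end, min(end + EXCURSION_SAMPLES, n)):
                exc[i] = offset
    exc[nan_mask] = 0.0
    return nan_mask, exc


def _pupil_segments(participant: ParticipantProfile, schedule: TrialSchedule,
                    rate: float):
    """Piecewise-exponential pupil level per (trial, condition), noiseless.

    Within each period the level approaches the condition target with a 1-s
    time constant, starting from the level reached at the end of the previous
    period.
    """
    tau = 1.0
    dt = 1.0 / rate
    level = 0.5 * (participant.pupil_bright + participant.pupil_dark)
    segments = {}
    for trial in range(schedule.n_trials):
        for condition, duration in (("bright", schedule.bright_duration),
                                    ("dark", schedule.dark_duration)):
            target = (participant.pupil_bright if condition == "bright"
                      else participant.pupil_dark)
            n = int(round(duration * rate))
            t = (np.arange(n) + 1) * dt
            seg = target + (level - target) * np.exp(-t / tau)
            segments[(trial, condition)] = seg
            if n:
                level = float(seg[-1])
    return segments


def generate_pupil_trace(participant: ParticipantProfile, schedule: TrialSchedule,
                         seed: int, *, sampling_rate: float = 100.0,
                         noise_frac: float = 0.01) -> pd.DataFrame:
    """Per-sample pupil-diameter series over the whole session.

    Columns: timestamp_s, pupil_mm, condition, phase, trial.  Bright and dark
    measurement-phase means sit at the profile's pupil diameters; adaptation
    carries the smooth exponential transition.  Multiplicative Gaussian noise
    of relative SD ``noise_frac`` is applied (0 for a deterministic trace).
    """
    if sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    segments = _pupil_segments(participant, schedule, sampling_rate)
    n_adapt = int(round(schedule.adaptation_duration * sampling_rate))
    rows = []
    t0 = 0.0
    dt = 1.0 / sampling_rate
    for trial in range(schedule.n_trials):
        for condition in ("bright", "dark"):
            seg = segments[(trial, condition)]
            if noise_frac > 0:
                seg = seg * (1.0 + rng.normal(0.0, noise_frac, size=len(seg)))
            t = t0 + np.arange(len(seg)) * dt
            phase = np.where(np.arange(len(seg)) < n_adapt, "adaptation", "measurement")
            rows.append(pd.DataFrame({
                "timestamp_s": t, "pupil_mm": seg, "condition": condition,
                "phase": phase, "trial": trial,
            }))
            t0 = t0 + len(seg) * dt
    return pd.concat(rows, ignore_index=True)


def generate_session(device: DeviceProfile, participant: ParticipantProfile,
                     schedule: TrialSchedule, seed: int,
                     target: tuple = (0.0, 0.0)):
    """Simulate one session; returns (recordings, ground_truth).

    One :class:`GazeRecording` per trial phase, in degree space, ordered
    (trial, bright-adaptation, bright-measurement, dark-adaptation,
    dark-measurement).  Measurement-phase samples are distributed around
    ``target + bias_bright`` in bright and ``target + bias_bright +
    psa_shift`` in dark; blinks invalidate samples in place (counts are
    conserved).  Identical inputs and seed reproduce identical output.
    """
    rng = np.random.default_rng(seed)
    rate = device.sampling_rate
    rho = device.ar_coefficient
    pupil = _pupil_segments(participant, schedule, rate)
    n_adapt = int(round(schedule.adaptation_duration * rate))

    target = np.asarray(target, dtype=float)
    bias = np.asarray(participant.bias_bright, dtype=float)
    shift = np.asarray(participant.psa_shift, dtype=float)

    recordings = []
    truth = GroundTruth(
        true_gaze_angle={
            "bright": tuple(target + bias),
            "dark": tuple(target + bias + shift),
        },
        injected_shift=tuple(shift),
        injected_loss_fraction=0.0,
    )
    n_nan_total = 0
    n_total = 0
    t0 = 0.0
    dt = 1.0 / rate
    for trial in range(schedule.n_trials):
        for condition in ("bright", "dark"):
            mean = target + bias + (shift if condition == "dark" else 0.0)
            pupil_seg = pupil[(trial, condition)]
            pupil_noise = rng.normal(0.0, 0.01, size=len(pupil_seg))
            for phase, duration in (("adaptation", schedule.adaptation_duration),
                                    ("measurement", schedule.measurement_duration)):
                n = int(round(duration * rate))
                sigma = device.noise_std * (3.0 if phase == "adaptation" else 1.0)
                x = mean[0] + _ar1_noise(rng, n, sigma, rho)
                y = mean[1] + _ar1_noise(rng, n, sigma, rho)
                nan_mask, exc = _inject_blinks(rng, n, device, duration)
                x = x + exc[:, 0]
                y = y + exc[:, 1]
                valid = ~nan_mask
                sl = slice(0, n) if phase == "adaptation" else slice(n_adapt, n_adapt + n)
                p = pupil_seg[sl] * (1.0 + pupil_noise[sl])
                rec = GazeRecording(
                    timestamps=t0 + np.arange(n) * dt,
                    x=x, y=y, valid=valid, pupil=p,
                    space=DEGREES, condition=condition, phase=phase,
                    trial_index=trial,
                )
                recordings.append(rec)
                key = (trial, condition, phase)
                truth.n_invalid_by_phase[key] = int(nan_mask.sum())
                truth.n_excursion_by_phase[key] = int(
                    np.any(exc != 0.0, axis=1).sum()
                )
                n_nan_total += int(nan_mask.sum())
                n_total += n
                t0 += n * dt
    truth.n_total = n_total
    truth.injected_loss_fraction = n_nan_total / n_total if n_total else 0.0
    return recordings, truth


# --------------------------------------------------------------------------- rendering


@dataclass
class FrameTruth:
    """Exact projected pixel positions for one rendered scene frame."""

    marker_pixel_positions: dict   # TL/TR/BL/BR/target -> (u, v)
    gaze_pixel: tuple
    true_distance: float


ROOM_GRAY = 0.16
TARGET_GRAY = 0.5
MARKER_RGB = (0.0, 0.7, 0.0)


def _project_screen_points(camera: CameraModel, points_mm: np.ndarray, distance: float):
    """Screen-plane mm (y up) -> distorted pixel coordinates."""
    xn = points_mm[:, 0] / distance
    yn = -points_mm[:, 1] / distance  # image y points down
    u, v = camera.project_normalized(xn, yn, distort=True)
    return np.column_stack([u, v])


def render_scene_frame(camera: CameraModel, screen: ScreenGeometry,
                       condition: str, gaze_angle=(0.0, 0.0), *,
                       distance_mm: float | None = None, supersample: int = 3,
                       noise_sigma: float = 0.0, seed: int = 0):
    """Render a scene-camera view of the stimulus display.

    The camera looks along its optical axis through the screen center at
    ``distance_mm`` (fronto-parallel).  Bright condition: white screen on a
    dim room; dark condition: black screen.  A gray bullseye-crosshair target
    (outer/inner angular diameters from ``screen``) sits at the center and
    four green discs at the marker positions.  Rendering is done by inverse
    mapping each (supersampled) pixel through the lens distortion onto the
    screen plane, so distortion and anti-aliasing are exact to the model.

    Returns ``(image_uint8_rgb, FrameTruth)`` where the truth carries the
    exact distorted projections of the five element centers and of the pixel
    corresponding to ``gaze_angle`` (degrees, x right, y up).
    """
    if condition not in ("bright", "dark"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    z = float(distance_mm if distance_mm is not None else screen.nominal_distance_mm)
    if z <= 0:
        raise ConfigurationError("distance must be positive")

    layout = screen.marker_layout
    # screen corners must project inside the image
    half_w, half_h = screen.width_mm / 2, screen.height_mm / 2
    corners = np.array([(-half_w, half_h), (half_w, half_h),
                        (-half_w, -half_h), (half_w, -half_h)])
    proj = _project_screen_points(camera, corners, z)
    if (np.any(proj[:, 0] < 0) or np.any(proj[:, 0] > camera.width - 1)
            or np.any(proj[:, 1] < 0) or np.any(proj[:, 1] > camera.height - 1)):
        raise GeometryError("screen is not fully inside the camera field of view")

    s = int(supersample)
    h, w = camera.height, camera.width
    # subpixel sample centers
    offs = (np.arange(s) + 0.5) / s - 0.5
    us = (np.arange(w)[:, None] + offs[None, :]).ravel()
    vs = (np.arange(h)[:, None] + offs[None, :]).ravel()
    uu, vv = np.meshgrid(us, vs)  # (h*s, w*s)
    xd = (uu - camera.cx) / camera.fx
    yd = (vv - camera.cy) / camera.fy
    xn, yn = camera.undistort_normalized(xd, yd, n_iter=25)
    X = xn * z
    Y = -yn * z

    img = np.empty((h * s, w * s, 3))
    img[:] = ROOM_GRAY
    on_screen = (np.abs(X) <= half_w) & (np.abs(Y) <= half_h)
    screen_rgb = 1.0 if condition == "bright" else 0.0
    img[on_screen] = screen_rgb

    # corner markers: green discs
    r_marker = screen.marker_diameter_mm / 2
    for cid in ("TL", "TR", "BL", "BR"):
        mx, my = layout[cid]
        inside = (X - mx) ** 2 + (Y - my) ** 2 <= r_marker ** 2
        img[inside] = MARKER_RGB

    # bullseye-crosshair target: gray outer disc, background-colored cross
    # arms of width = inner diameter, gray inner dot
    r_outer = math.tan(math.radians(screen.target_outer_deg / 2)) * z
    r_inner = math.tan(math.radians(screen.target_inner_deg / 2)) * z
    d2 = X ** 2 + Y ** 2
    outer = d2 <= r_outer ** 2
    cross = (np.abs(X) <= r_inner) | (np.abs(Y) <= r_inner)
    inner = d2 <= r_inner ** 2
    img[outer] = TARGET_GRAY
    img[outer & cross] = screen_rgb
    img[inner] = TARGET_GRAY

    # average subsamples -> anti-aliased pixel values
    img = img.reshape(h, s, w, s, 3).mean(axis=(1, 3))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img8 = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    element_mm = np.array([layout[c] for c in ("TL", "TR", "BL", "BR", "target")])
    element_px = _project_screen_points(camera, element_mm, z)
    gx = math.tan(math.radians(gaze_angle[0])) * z
    gy = math.tan(math.radians(gaze_angle[1])) * z
    gaze_px = _project_screen_points(camera, np.array([[gx, gy]]), z)[0]
    truth = FrameTruth(
        marker_pixel_positions={
            c: tuple(element_px[i]) for i, c in enumerate(("TL", "TR", "BL", "BR", "target"))
        },
        gaze_pixel=tuple(gaze_px),
        true_distance=z,
    )
    return img8, truth
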