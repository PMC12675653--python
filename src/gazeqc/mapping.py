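"""Scene-camera gaze mapping: pixels to screen-centered degrees of visual angle.

The chain mirrors a head-mounted recording pipeline: detect the five screen
elements in a scene frame, undistort everything to an ideal pinhole frame,
derive a mm-per-pixel scaling factor from known marker spacing, estimate the
viewing distance from known marker size and focal length, and convert gaze
pixel offsets from the detected target into degrees via arctan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.color import rgb2gray
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk
from skimage.segmentation import clear_border
from sklearn.cluster import KMeans

from .errors import (
    AmbiguousDetection,
    ConfigurationError,
    DegenerateGeometry,
    DomainError,
    MarkersNotFound,
)

log = logging.getLogger(__name__)

CORNER_IDS = ("TL", "TR", "BL", "BR")


# --------------------------------------------------------------------------- types


@dataclass(frozen=True)
class CameraModel:
    """Pinhole scene camera with Brown-Conrady distortion (k1, k2, p1, p2, k3)."""

    fx: float
    fy: float
    cx: float
    cy: float
    distortion: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    width: int = 1280
    height: int = 720

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ConfigurationError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ConfigurationError("principal point must lie inside the image")
        d = tuple(self.distortion) + (0.0,) * 5
        object.__setattr__(self, "distortion", d[:5])

    # normalized <-> pixel helpers -----------------------------------------

    def distort_normalized(self, xn: np.ndarray, yn: np.ndarray):
        """Apply the forward distortion model to ideal normalized coordinates."""
        k1, k2, p1, p2, k3 = self.distortion
        r2 = xn * xn + yn * yn
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        xd = xn * radial + 2.0 * p1 * xn * yn + p2 * (r2 + 2.0 * xn * xn)
        yd = yn * radial + p1 * (r2 + 2.0 * yn * yn) + 2.0 * p2 * xn * yn
        return xd, yd

    def undistort_normalized(self, xd: np.ndarray, yd: np.ndarray, *, n_iter: int = 50,
                             tol: float = 1e-12):
        """Invert the distortion model by fixed-point iteration on (xn, yn)."""
        k1, k2, p1, p2, k3 = self.distortion
        xn, yn = np.array(xd, float, copy=True), np.array(yd, float, copy=True)
        for _ in range(n_iter):
            r2 = xn * xn + yn * yn
            radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
            dx = 2.0 * p1 * xn * yn + p2 * (r2 + 2.0 * xn * xn)
            dy = p1 * (r2 + 2.0 * yn * yn) + 2.0 * p2 * xn * yn
            xn_new = (xd - dx) / radial
            yn_new = (yd - dy) / radial
            if np.all((xn_new - xn) ** 2 + (yn_new - yn) ** 2 < tol * tol):
                xn, yn = xn_new, yn_new
                break
            xn, yn = xn_new, yn_new
        return xn, yn

    def project_normalized(self, xn, yn, *, distort: bool = True):
        """Ideal normalized coordinates -> pixel coordinates."""
        if distort:
            xn, yn = self.distort_normalized(np.asarray(xn, float), np.asarray(yn, float))
        u = self.cx + self.fx * np.asarray(xn, float)
        v = self.cy + self.fy * np.asarray(yn, float)
        return u, v


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen and marker layout, mm, screen-centered, y up."""

    width_mm: float = 476.0
    height_mm: float = 268.0
    marker_inset_mm: float = 20.0
    marker_diameter_mm: float = 20.0
    nominal_distance_mm: float = 930.0
    target_outer_deg: float = 0.6
    target_inner_deg: float = 0.2

    def __post_init__(self):
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ConfigurationError("screen dimensions must be positive")
        if self.nominal_distance_mm <= 0:
            raise ConfigurationError("nominal distance must be positive")
        hx = self.width_mm / 2 - self.marker_inset_mm
        hy = self.height_mm / 2 - self.marker_inset_mm
        if hx <= 0 or hy <= 0:
            raise ConfigurationError("markers must lie within the screen bounds")

    @property
    def marker_layout(self) -> dict:
        """Physical marker centers (mm, y up) keyed TL/TR/BL/BR plus target."""
        hx = self.width_mm / 2 - self.marker_inset_mm
        hy = self.height_mm / 2 - self.marker_inset_mm
        return {
            "TL": (-hx, hy),
            "TR": (hx, hy),
            "BL": (-hx, -hy),
            "BR": (hx, -hy),
            "target": (0.0, 0.0),
        }


@dataclass
class MarkerDetection:
    """Pixel locations of the central target and four corner reference points."""

    corner_points: dict          # id -> (u, v) pixel center
    target_point: tuple          # (u, v)
    corner_diameters_px: dict    # id -> equivalent diameter in pixels
    frame_index: int = 0
    quality: float = 0.0
    undistorted: bool = False

    def __post_init__(self):
        missing = set(CORNER_IDS) - set(self.corner_points)
        if missing:
            raise ConfigurationError(f"missing corner identities: {sorted(missing)}")

    def points(self) -> np.ndarray:
        """5x2 array ordered TL, TR, BL, BR, target."""
        pts = [self.corner_points[c] for c in CORNER_IDS] + [self.target_point]
        return np.asarray(pts, dtype=float)


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-recording detection thresholds (selected manually in practice).

    ``threshold`` is on the [0, 1] grayscale scale; ``None`` selects Otsu's
    method as an automatic fallback.  ``polarity`` says whether the screen
    elements are darker or brighter than their surroundings; ``auto`` decides
    from the median image intensity.
    """

    threshold: float | None = 0.3
    polarity: str = "auto"  # {'dark', 'bright', 'auto'}
    min_area_px: float = 4.0
    max_area_fraction: float = 0.1
    exclude_border: bool = True


# --------------------------------------------------------------------------- detection


def _foreground_signal(frame: np.ndarray, config: ThresholdConfig) -> np.ndarray:
    if frame.ndim == 3:
        gray = rgb2gray(frame[..., :3])
    else:
        gray = np.asarray(frame, dtype=float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    return (1.0 - gray) if config.polarity == "dark" else gray


def detect_markers(frame: np.ndarray, config: ThresholdConfig | None = None,
                   frame_index: int = 0) -> MarkerDetection:
    """Locate the five screen elements in a scene frame.

    Grayscale conversion, thresholding and connected-component extraction
    produce candidate regions (the bullseye-crosshair target fragments into
    several); K-means with five fixed clusters groups them, and corner
    identities are assigned by quadrant relative to the centroid of all five
    cluster centers.  Region centroids and areas are coverage-weighted using
    the local intensity profile, which keeps them sub-pixel accurate on
    anti-aliased frames.
    """
    config = config or ThresholdConfig()
    if config.polarity == "auto":
        # elements darker than a bright screen, or brighter than a dark one:
        # try both and keep the first interpretation that yields five clusters
        first_err = None
        for polarity in ("dark", "bright"):
            try:
                return detect_markers(frame, replace(config, polarity=polarity),
                                      frame_index)
            except (MarkersNotFound, AmbiguousDetection) as err:
                first_err = first_err or err
        raise first_err
    signal = _foreground_signal(frame, config)
    if config.threshold is None:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(signal)
    else:
        thr = float(config.threshold)
    binary = signal > thr
    if config.exclude_border:
        binary = clear_border(binary)
    labels = label(binary)
    h, w = signal.shape
    max_area = config.max_area_fraction * h * w

    centroids, areas = [], []
    struct = disk(2)
    for region in regionprops(labels):
        if region.area < config.min_area_px or region.area > max_area:
            continue
        rmin, cmin, rmax, cmax = region.bbox
        pad = 3
        rmin, cmin = max(rmin - pad, 0), max(cmin - pad, 0)
        rmax, cmax = min(rmax + pad, h), min(cmax + pad, w)
        patch = signal[rmin:rmax, cmin:cmax]
        mask = labels[rmin:rmax, cmin:cmax] == region.label
        dil = dilation(mask, struct)
        ring = dil & ~mask
        fg = float(np.median(patch[mask]))
        bg = float(np.median(patch[ring])) if ring.any() else 0.0
        if fg <= bg:  # degenerate contrast: fall back to binary mass
            alpha = mask.astype(float)
        else:
            alpha = np.clip((patch - bg) / (fg - bg), 0.0, 1.0) * dil
        m = alpha.sum()
        rr, cc = np.nonzero(dil)
        v = (alpha[rr, cc] * rr).sum() / m + rmin
        u = (alpha[rr, cc] * cc).sum() / m + cmin
        centroids.append((u, v))
        areas.append(m)

    if len(centroids) < 5:
        raise MarkersNotFound(f"found {len(centroids)} candidate regions, need >= 5")

    pts = np.asarray(centroids)
    wts = np.asarray(areas)
    if len(pts) == 5:
        assignment = np.arange(5)
    else:
        km = KMeans(n_clusters=5, n_init=10, random_state=0)
        assignment = km.fit_predict(pts, sample_weight=wts)

    centers, cluster_area, spread = [], [], []
    for c in range(5):
        m = assignment == c
        if not m.any():
            raise MarkersNotFound("clustering produced an empty group")
        wa = wts[m]
        ctr = (pts[m] * wa[:, None]).sum(axis=0) / wa.sum()
        centers.append(ctr)
        cluster_area.append(wa.sum())
        spread.append(float((np.linalg.norm(pts[m] - ctr, axis=1) * wa).sum() / wa.sum()))
    centers = np.asarray(centers)
    cluster_area = np.asarray(cluster_area)

    diam = 2.0 * np.sqrt(cluster_area / np.pi)
    dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    if dists.min() < diam.max():
        raise AmbiguousDetection(
            f"two clusters are {dists.min():.1f} px apart, closer than the "
            f"marker diameter {diam.max():.1f} px"
        )

    # identity: target = cluster nearest the centroid of all five; corners by quadrant
    hub = centers.mean(axis=0)
    target_idx = int(np.argmin(np.linalg.norm(centers - hub, axis=1)))
    corner_idx = [i for i in range(5) if i != target_idx]
    hub4 = centers[corner_idx].mean(axis=0)
    names = []
    for i in corner_idx:
        du, dv = centers[i] - hub4
        names.append(("T" if dv < 0 else "B") + ("L" if du < 0 else "R"))
    if len(set(names)) != 4:
        # quadrant tie: break by distance to the image corners (optimal matching)
        from scipy.optimize import linear_sum_assignment

        image_corner = np.array([(0, 0), (w, 0), (0, h), (w, h)], dtype=float)
        cost = np.linalg.norm(
            centers[corner_idx][:, None, :] - image_corner[None, :, :], axis=-1
        )
        _, cols = linear_sum_assignment(cost)
        names = [CORNER_IDS[j] for j in cols]
    corner_points = {n: tuple(centers[i]) for n, i in zip(names, corner_idx)}
    corner_diam = {n: float(diam[i]) for n, i in zip(names, corner_idx)}

    return MarkerDetection(
        corner_points=corner_points,
        target_point=tuple(centers[target_idx]),
        corner_diameters_px=corner_diam,
        frame_index=frame_index,
        quality=float(np.mean(spread)),
        undistorted=False,
    )


# --------------------------------------------------------------------------- undistortion


def undistort_points(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Map observed pixel coordinates to ideal-pinhole pixel coordinates.

    Identity when all distortion coefficients are zero.  NaN inputs propagate.
    Raises :class:`DomainError` when the iterative inverse fails to converge
    (point outside the invertible distortion domain).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xd = (pts[:, 0] - camera.cx) / camera.fx
    yd = (pts[:, 1] - camera.cy) / camera.fy
    if not any(camera.distortion):
        out = pts.copy()
        return out if np.asarray(points).ndim > 1 else out[0]
    xn, yn = camera.undistort_normalized(xd, yd)
    # verify convergence by re-applying the forward model
    xc, yc = camera.distort_normalized(xn, yn)
    finite = np.isfinite(xd) & np.isfinite(yd)
    err = np.hypot(xc - xd, yc - yd)
    if np.any(err[finite] * max(camera.fx, camera.fy) > 1e-3):
        raise DomainError("undistortion did not converge; point outside invertible domain")
    out = np.column_stack([camera.cx + camera.fx * xn, camera.cy + camera.fy * yn])
    return out if np.asarray(points).ndim > 1 else out[0]


def undistort_detection(det: MarkerDetection, camera: CameraModel) -> MarkerDetection:
    """Undistorted copy of a detection.

    Marker centers are mapped through :func:`undistort_points`; apparent
    diameters are rescaled by the local isotropic Jacobian of the
    undistortion map (finite differences), so size-based distance estimates
    stay consistent with the ideal-pinhole frame.
    """
    if det.undistorted:
        return det
    pts = det.points()
    und = undistort_points(pts, camera)
    corner_points = {c: tuple(und[i]) for i, c in enumerate(CORNER_IDS)}
    diam = {}
    eps = 0.5
    for i, c in enumerate(CORNER_IDS):
        p = pts[i]
        probe = np.array([p, p + (eps, 0), p + (0, eps)])
        q = undistort_points(probe, camera)
        jac = np.column_stack([(q[1] - q[0]) / eps, (q[2] - q[0]) / eps])
        scale = float(np.sqrt(abs(np.linalg.det(jac))))
        diam[c] = det.corner_diameters_px[c] * scale
    return replace(
        det,
        corner_points=corner_points,
        target_point=tuple(und[4]),
        corner_diameters_px=diam,
        undistorted=True,
    )


# --------------------------------------------------------------------------- geometry


def compute_scaling_factor(detection: MarkerDetection, screen: ScreenGeometry) -> float:
    """Millimeters per pixel from known vs. apparent marker spacing.

    Averages the physical/apparent distance ratio over all six corner-marker
    pairs, which damps the influence of any single noisy detection.
    """
    layout = screen.marker_layout
    ratios = []
    for i, a in enumerate(CORNER_IDS):
        for b in CORNER_IDS[i + 1:]:
            phys = np.hypot(layout[a][0] - layout[b][0], layout[a][1] - layout[b][1])
            pa, pb = detection.corner_points[a], detection.corner_points[b]
            app = np.hypot(pa[0] - pb[0], pa[1] - pb[1])
            if app <= 1e-9:
                raise DegenerateGeometry(f"markers {a} and {b} coincide in the image")
            ratios.append(phys / app)
    return float(np.mean(ratios))


def estimate_viewing_distance(detection: MarkerDetection, screen: ScreenGeometry,
                              camera: CameraModel) -> float:
    """Viewing distance in mm from marker size, via the pinhole model.

    distance = focal_length_px * physical_diameter_mm / apparent_diameter_px,
    averaged over the four corner markers.  A >10% spread between markers is
    logged as a warning (oblique viewing), not raised.
    """
    f = 0.5 * (camera.fx + camera.fy)
    estimates = []
    for c in CORNER_IDS:
        d_px = detection.corner_diameters_px.get(c, 0.0)
        if d_px <= 1e-9:
            raise DegenerateGeometry(f"marker {c} has zero apparent size")
        estimates.append(f * screen.marker_diameter_mm / d_px)
    estimates = np.asarray(estimates)
    mean = float(estimates.mean())
    if (estimates.max() - estimates.min()) > 0.1 * mean:
        log.warning("distance estimates disagree by >10%%: %s", estimates)
    return mean


def map_gaze_to_degrees(gaze_px: np.ndarray, detection: MarkerDetection,
                        scale: float, distance: float) -> np.ndarray:
    """Scene-camera pixels -> screen-centered degrees of visual angle.

    Per axis: subtract the detected target center, convert to mm with the
    scaling factor, then arctan against the viewing distance.  Output is
    x-positive-rightward, y-positive-upward (the image y-down convention is
    flipped here and only here).  Non-finite gaze coordinates propagate as
    NaN so data-loss accounting downstream still sees them.
    """
    if scale <= 0 or distance <= 0:
        raise ConfigurationError("scale and distance must be positive")
    g = np.atleast_2d(np.asarray(gaze_px, dtype=float))
    dx_mm = (g[:, 0] - detection.target_point[0]) * scale
    dy_mm = (g[:, 1] - detection.target_point[1]) * scale
    x_deg = np.degrees(np.arctan2(dx_mm, distance))
    y_deg = -np.degrees(np.arctan2(dy_mm, distance))
    x_deg = np.where(np.isfinite(g[:, 0]), x_deg, np.nan)
    y_deg = np.where(np.isfinite(g[:, 1]), y_deg, np.nan)
    out = np.column_stack([x_deg, y_deg])
    return out if np.asarray(gaze_px).ndim > 1 else out[0]


def eyelink_pixels_to_degrees(gaze_px: np.ndarray, screen_center_px,
                              resolution) -> np.ndarray:
    """Desktop-tracker conversion: (gaze - screen_center) / pixels-per-degree.

    Linear per axis, no sign flip (matches the device's own convention);
    NaN propagates.
    """
    res = np.broadcast_to(np.asarray(resolution, dtype=float), (2,))
    if np.any(res <= 0):
        raise ConfigurationError("resolution must be positive on both axes")
    g = np.atleast_2d(np.asarray(gaze_px, dtype=float))
    c = np.asarray(screen_center_px, dtype=float)
    out = (g - c) / res
    return out if np.asarray(gaze_px).ndim > 1 else out[0]
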