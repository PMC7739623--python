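"""Functional base-of-support (BOS) geometry.

The functional BOS of one foot is the convex region in which a person
can place their centre of pressure under at least half body weight
without rolling the foot.  It is measured once from COP-excursion
recordings, normalized by foot width ``w`` and length ``l`` into a
template polygon, and then rescaled onto each participant's feet.  The
whole-body BOS is the convex hull of both feet's scaled polygons, and
balance metrics are signed distances to its boundary (positive inside).

The foot frame follows the ankle/metatarsal marker construction: the
origin sits between the two ankle markers (FAL lateral, TAM medial),
y-hat points toward the midpoint of the first and fifth metatarsal
markers, x-hat is the component of (TAM - FAL) perpendicular to y-hat,
and z-hat completes the (possibly left-handed-looking, for a right
foot) triad via x cross y.  A calibration transform then anchors the
origin to the ground plane with z-hat up; right-foot COP profiles are
reflected about y-hat before averaging so the template lives in
left-foot normalized space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial.transform import Rotation
from shapely.geometry import MultiPoint, Polygon

FLAT_FOOT_TOL = 0.015  # m: allowed tilt displacement of either foot axis
TEMPLATE_CENTER = (-0.15, 0.3)  # ray-averaging anchor, left-foot normalized
ANKLE_MARKERS = ("FAL", "TAM")
FOOT_MARKERS = ("FAL", "TAM", "FM1", "FM2", "FM5", "FCC")


@dataclass
class FootFrame:
    """Anatomical foot frame (unit axes, right-handed by construction)."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    side: str = "left"

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes expressed in the lab frame."""
        return np.column_stack([self.x, self.y, self.z])


def foot_frame(markers: dict, side: str = "left") -> FootFrame:
    """Build the anatomical foot frame from the six foot markers.

    ``markers`` maps the short names FAL/TAM/FM1/FM2/FM5/FCC to single
    (3,) positions (e.g. means over a calibration window).
    """
    for name in FOOT_MARKERS:
        if name not in markers:
            raise ValueError(f"missing foot marker {name}")
    fal = np.asarray(markers["FAL"], float)
    tam = np.asarray(markers["TAM"], float)
    origin = 0.5 * (fal + tam)
    toe_mid = 0.5 * (np.asarray(markers["FM1"], float) + np.asarray(markers["FM5"], float))
    yv = toe_mid - origin
    ny = np.linalg.norm(yv)
    if ny < 1e-9:
        raise ValueError("degenerate foot markers: ankle and toe midpoints coincide")
    yhat = yv / ny
    xv = tam - fal
    xv = xv - (xv @ yhat) * yhat
    nx = np.linalg.norm(xv)
    if nx < 1e-9:
        raise ValueError("degenerate foot markers: ankle markers colinear with y")
    xhat = xv / nx
    zhat = np.cross(xhat, yhat)
    return FootFrame(origin=origin, x=xhat, y=yhat, z=zhat, side=side)


def calibrate_foot_frame(frame: FootFrame) -> FootFrame:
    """Anchor a foot frame to the ground plane with z-hat pointing up.

    The heading (y-hat) is kept, flattened to horizontal; x-hat is
    rebuilt as y cross z so both feet share an up-pointing, world-
    consistent triad (which is why right-foot profiles need reflecting).
    """
    zw = np.array([0.0, 0.0, 1.0])
    yh = frame.y - (frame.y @ zw) * zw
    n = np.linalg.norm(yh)
    if n < 1e-9:
        raise ValueError("foot y axis is vertical; cannot calibrate")
    yh /= n
    xh = np.cross(yh, zw)
    origin = frame.origin.copy()
    origin[2] = 0.0
    return FootFrame(origin=origin, x=xh, y=yh, z=zw, side=frame.side)


def foot_dimensions(markers: dict, side: str = "left") -> tuple[float, float]:
    """Foot width and length from the anatomical frame and markers."""
    fr = foot_frame(markers, side)
    fal = np.asarray(markers["FAL"], float)
    tam = np.asarray(markers["TAM"], float)
    fm1 = np.asarray(markers["FM1"], float)
    fm5 = np.asarray(markers["FM5"], float)
    w = fr.x @ (0.5 * (tam - fal) + 0.5 * (fm1 - fm5))
    ell = fr.y @ (np.asarray(markers["FM2"], float) - np.asarray(markers["FCC"], float))
    if w <= 0 or ell <= 0:
        raise ValueError(f"non-positive foot dimensions (w={w:.4f}, l={ell:.4f})")
    return float(w), float(ell)


def foot_is_flat(foot_rotation: np.ndarray, w: float, ell: float,
                 tol: float = FLAT_FOOT_TOL) -> np.ndarray:
    """Flat-foot test from the X-Y'-Z'' Euler tilt of the foot.

    ``foot_rotation`` is the rotation of the foot relative to its flat
    calibration pose, expressed in the calibrated foot frame; it may be
    a single (3, 3) matrix or a (T, 3, 3) series.  The foot counts as
    flat when both tilt displacements w*sin(psi_X) and l*sin(theta_Y)
    stay within the compression allowance (inclusive bound).
    """
    R = np.asarray(foot_rotation, float)
    single = R.ndim == 2
    ang = Rotation.from_matrix(R.reshape(-1, 3, 3)).as_euler("XYZ")
    psi_x, theta_y = ang[:, 0], ang[:, 1]
    ok = (w * np.abs(np.sin(psi_x)) <= tol) & (ell * np.abs(np.sin(theta_y)) <= tol)
    return bool(ok[0]) if single else ok


# ------------------------------------------------------------------ polygons


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """CCW vertices of the convex hull of 2D points (no closing repeat)."""
    hull = MultiPoint(np.asarray(points, float)).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("degenerate hull (points are colinear)")
    xy = np.asarray(hull.exterior.coords)[:-1]
    # shapely returns CW for convex_hull of MultiPoint in some versions
    area = 0.5 * np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    return xy if area > 0 else xy[::-1]


@dataclass
class BosPolygon:
    """Convex ground-plane polygon (vertices in metres, CCW)."""

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self._poly = Polygon(self.vertices)
        if self._poly.area <= 0:
            raise ValueError("degenerate BOS polygon")

    @property
    def area(self) -> float:
        return self._poly.area

    @property
    def shapely(self) -> Polygon:
        return self._poly


@dataclass
class BosTemplate:
    """Normalized convex foot polygon (left-foot space, unitless)."""

    vertices: np.ndarray  # (n, 2), coordinates (x/w, y/l), CCW
    center: np.ndarray  # ray-averaging anchor

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.center = np.asarray(self.center, float)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "vertices": self.vertices.tolist(),
            "center": self.center.tolist(),
        }, indent=1))

    @classmethod
    def load(cls, path) -> "BosTemplate":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["vertices"]), np.asarray(d["center"]))


def default_template() -> BosTemplate:
    """The packaged template, built from synthetic COP-excursion data."""
    with resources.files("stsbalance").joinpath("data/bos_template.json").open() as fh:
        d = json.load(fh)
    return BosTemplate(np.asarray(d["vertices"]), np.asarray(d["center"]))


@dataclass
class FootCopProfile:
    """Per-foot COP samples resolved in the calibrated foot frame."""

    cop_local: np.ndarray  # (N, 2) m
    force: np.ndarray  # (N,) N, plate normal force
    flat: np.ndarray  # (N,) bool
    width: float
    length: float
    side: str = "left"


def _ray_radii(vertices: np.ndarray, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from an interior point to a convex polygon along each ray."""
    a = vertices
    b = np.roll(vertices, -1, axis=0)
    edge = b - a
    normals = np.column_stack([edge[:, 1], -edge[:, 0]])  # outward for CCW
    d = np.column_stack([np.cos(angles), np.sin(angles)])  # (K, 2)
    num = np.einsum("ej,ej->e", normals, a - center)  # (E,)
    if np.any(num < -1e-12):
        raise ValueError("ray-averaging center lies outside a profile polygon")
    den = d @ normals.T  # (K, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num[None, :] / den
    t = np.where(den > 1e-12, t, np.inf)
    return t.min(axis=1)


def build_template(
    profiles,
    body_weight: float,
    center=TEMPLATE_CENTER,
    n_rays: int = 360,
) -> BosTemplate:
    """Average per-foot COP hulls into the normalized BOS template.

    Each profile is filtered to samples where the foot is flat and the
    normal force exceeds half body weight, normalized by that foot's
    width and length, reflected about y-hat for right feet, and hulled.
    The hulls are averaged radially about the common ``center`` and the
    ray-average is convexified.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one foot profile")
    center = np.asarray(center, float)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    radii = []
    for p in profiles:
        valid = np.asarray(p.flat, bool) & (np.asarray(p.force, float) > 0.5 * body_weight)
        pts = np.asarray(p.cop_local, float)[valid]
        pts = pts[np.isfinite(pts).all(axis=1)]
        if pts.shape[0] < 3:
            raise ValueError("fewer than 3 valid COP points in a foot profile")
        pts = pts / np.array([p.width, p.length])
        if p.side == "right":
            pts = pts * np.array([-1.0, 1.0])
        radii.append(_ray_radii(_hull_vertices(pts), center, angles))
    r_mean = np.mean(radii, axis=0)
    verts = center + r_mean[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    return BosTemplate(_hull_vertices(verts), center)


def scale_template(
    template: BosTemplate, w: float, ell: float, frame: FootFrame
) -> BosPolygon:
    """Place the normalized template onto one foot in the ground plane.

    ``frame`` must be a calibrated (ground-anchored) foot frame; right
    feet use the template reflected back about y-hat.
    """
    v = template.vertices.copy()
    if frame.side == "right":
        v[:, 0] *= -1.0
    local = v * np.array([w, ell])
    world = (frame.origin[:2]
             + local[:, :1] * frame.x[:2]
             + local[:, 1:] * frame.y[:2])
    return BosPolygon(_hull_vertices(world))


def whole_body_bos(left: BosPolygon, right: BosPolygon) -> BosPolygon:
    """Convex hull of both feet's BOS polygons."""
    pts = np.vstack([left.vertices, right.vertices])
    return BosPolygon(_hull_vertices(pts))


def signed_distance(points: np.ndarray, polygon: BosPolygon) -> np.ndarray:
    """Signed distance to the BOS boundary: positive inside, negative out."""
    pts = np.asarray(points, float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    finite = np.isfinite(pts).all(axis=1)
    out = np.full(pts.shape[0], np.nan)
    if finite.any():
        geoms = shapely.points(pts[finite])
        dist = shapely.distance(geoms, polygon.shapely.exterior)
        inside = shapely.covers(polygon.shapely, geoms)
        out[finite] = np.where(inside, dist, -dist)
    return float(out[0]) if single else out


# ---------------------------------------------------- profiles from a trial


def foot_markers_from_trial(trial, side: str) -> dict:
    """The six foot-marker trajectories of one foot, short names."""
    prefix = side[0].upper()
    return {name: trial.markers[prefix + name] for name in FOOT_MARKERS}


def calibrated_foot_frames(trial, cal_window_s: float = 1.0) -> dict:
    """Per-foot calibrated frames from a still calibration window."""
    n = max(2, int(round(cal_window_s * trial.f_mocap)))
    frames = {}
    for side in ("left", "right"):
        mks = foot_markers_from_trial(trial, side)
        mean_mks = {k: v[:n].mean(axis=0) for k, v in mks.items()}
        frames[side] = calibrate_foot_frame(foot_frame(mean_mks, side))
    return frames


def extract_cop_profiles(trial, cal_window_s: float = 1.0) -> list:
    """Resolve foot-plate COP samples into per-foot profiles.

    Samples are assigned to the foot whose frame origin is nearest.
    Flatness is judged from the rigid rotation of each foot's marker
    cluster relative to the calibration window.
    """
    from .kinematics import rigid_pose_fit  # local import to avoid a cycle

    n = max(2, int(round(cal_window_s * trial.f_mocap)))
    profiles = []
    cop = np.asarray(trial.foot_plate.cop, float)
    force = np.asarray(trial.foot_plate.fz, float)
    frames = calibrated_foot_frames(trial, cal_window_s)
    # assignment by nearest foot origin
    origins = np.stack([frames[s].origin[:2] for s in ("left", "right")])
    d2 = ((cop[:, None, :] - origins[None, :, :]) ** 2).sum(axis=2)
    nearest = np.nanargmin(np.where(np.isfinite(d2), d2, np.inf), axis=1)
    for idx, side in enumerate(("left", "right")):
        fr = frames[side]
        mks = foot_markers_from_trial(trial, side)
        mean_mks = {k: v[:n].mean(axis=0) for k, v in mks.items()}
        w, ell = foot_dimensions(mean_mks, side)
        local = np.stack([mean_mks[k] - fr.origin for k in FOOT_MARKERS])
        world = np.stack([mks[k] for k in FOOT_MARKERS], axis=1)
        R, _ = rigid_pose_fit(local, world)
        F = fr.rotation
        R_foot = np.einsum("ji,tjk,kl->til", F, R, F)
        flat = foot_is_flat(R_foot, w, ell)
        rel = cop - fr.origin[:2]
        cop_local = np.column_stack([rel @ fr.x[:2], rel @ fr.y[:2]])
        mine = nearest == idx
        profiles.append(FootCopProfile(
            cop_local=cop_local[mine], force=force[mine], flat=flat[mine],
            width=w, length=ell, side=side,
        ))
    return profiles
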