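"""Whole-body kinematic state from per-segment states.

Every balance metric downstream consumes the same aggregate quantities:
the whole-body COM position and velocity, the inertia tensor about the
COM, the angular momentum about the COM, and the *average angular
velocity* -- the angular velocity of the single rigid body that carries
the same angular momentum as the multibody system,

    J_C  w_avg = H_C,
    J_C  = sum_i  J_i + m_i ((r_i . r_i) I - r_i r_i^T),
    H_C  = sum_i  J_i w_i + r_i x (m_i v_i),

with r_i, v_i the position/velocity of segment i's COM relative to the
whole-body COM, all in the inertial frame.

All operations broadcast over a leading time axis, so a ``SegmentState``
may hold a single sample (shape ``(3,)``) or a whole series ``(T, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .recording import ForcePlate, TrialRecording


class TrialRejectedError(Exception):
    """Raised when a recording cannot be analyzed (e.g. long marker gaps)."""


# --------------------------------------------------------------- aggregates


@dataclass
class SegmentState:
    """State of one body segment: mass, COM pos/vel, inertia, angular vel."""

    m: float
    r: np.ndarray  # (..., 3) COM position, m
    v: np.ndarray  # (..., 3) COM velocity, m/s
    J: np.ndarray  # (..., 3, 3) inertia about COM, world frame, kg m^2
    w: np.ndarray  # (..., 3) angular velocity, rad/s

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("segment mass must be positive")


def whole_body_com(segments) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted mean COM position and velocity."""
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    mtot = sum(s.m for s in segments)
    r = sum(s.m * np.asarray(s.r, float) for s in segments) / mtot
    v = sum(s.m * np.asarray(s.v, float) for s in segments) / mtot
    return r, v


def inertia_about_com(segments, r_com: np.ndarray | None = None) -> np.ndarray:
    """Whole-body inertia about the COM (world frame, parallel-axis sum)."""
    segments = list(segments)
    if r_com is None:
        r_com, _ = whole_body_com(segments)
    eye = np.eye(3)
    out = None
    for s in segments:
        d = np.asarray(s.r, float) - r_com  # (..., 3)
        d2 = np.einsum("...i,...i->...", d, d)
        outer = np.einsum("...i,...j->...ij", d, d)
        term = np.asarray(s.J, float) + s.m * (d2[..., None, None] * eye - outer)
        out = term if out is None else out + term
    return out


def angular_momentum_about_com(
    segments,
    r_com: np.ndarray | None = None,
    v_com: np.ndarray | None = None,
) -> np.ndarray:
    """Whole-body angular momentum about the COM (world frame)."""
    segments = list(segments)
    if r_com is None or v_com is None:
        r_com, v_com = whole_body_com(segments)
    out = None
    for s in segments:
        d = np.asarray(s.r, float) - r_com
        dv = np.asarray(s.v, float) - v_com
        term = np.einsum("...ij,...j->...i", np.asarray(s.J, float), np.asarray(s.w, float))
        term = term + np.cross(d, s.m * dv)
        out = term if out is None else out + term
    return out


def average_angular_velocity(
    J_C: np.ndarray, H_C: np.ndarray, cond_max: float = 1e12
) -> np.ndarray:
    """Solve J_C w_avg = H_C per sample; ill-conditioned samples become NaN."""
    J_C = np.asarray(J_C, float)
    H_C = np.asarray(H_C, float)
    w = np.linalg.solve(J_C, H_C[..., None])[..., 0]
    cond = np.linalg.cond(J_C)
    bad = ~(cond < cond_max)
    if np.any(bad):
        w = np.where(np.asarray(bad)[..., None], np.nan, w)
    return w


@dataclass
class WholeBodyState:
    """Aggregate state series used by every balance metric."""

    r_C: np.ndarray  # (..., 3) COM
    v_C: np.ndarray  # (..., 3)
    J_C: np.ndarray  # (..., 3, 3)
    H_C: np.ndarray  # (..., 3)
    w_avg: np.ndarray  # (..., 3)

    @property
    def com_gp(self) -> np.ndarray:
        """Ground projection of the COM (x, y)."""
        return self.r_C[..., :2]

    @property
    def h(self) -> np.ndarray:
        """COM height above the ground plane."""
        return self.r_C[..., 2]

    @classmethod
    def from_segments(cls, segments) -> "WholeBodyState":
        segments = list(segments)
        r, v = whole_body_com(segments)
        J = inertia_about_com(segments, r)
        H = angular_momentum_about_com(segments, r, v)
        w = average_angular_velocity(J, H)
        return cls(r_C=r, v_C=v, J_C=J, H_C=H, w_avg=w)


# -------------------------------------------------------- signal processing


def central_difference(x: np.ndarray, dt: float) -> np.ndarray:
    """Central differences along axis 0, one-sided at the ends."""
    x = np.asarray(x, float)
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    d[0] = (x[1] - x[0]) / dt
    d[-1] = (x[-1] - x[-2]) / dt
    return d


def _fill_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs; reject runs longer than ``max_gap``."""
    x = x.copy()
    for col in range(x.shape[1]):
        col_x = x[:, col]
        bad = ~np.isfinite(col_x)
        if not bad.any():
            continue
        # longest run of consecutive NaNs
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
        if runs.size and runs.max() > max_gap:
            raise TrialRejectedError("marker gap exceeds the allowed span")
        idx = np.arange(len(col_x))
        col_x[bad] = np.interp(idx[bad], idx[~bad], col_x[~bad])
        x[:, col] = col_x
    return x


def _bidirectional_lowpass(x: np.ndarray, cutoff_hz: float, fs: float, order: int = 4):
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=0)


def preprocess(
    trial: TrialRecording,
    cutoff_hz: float | None = 10.0,
    order: int = 4,
    max_gap_s: float = 0.1,
) -> TrialRecording:
    """Zero-phase low-pass filter markers and forces; decimate forces.

    Marker and force streams are filtered with a bidirectional (forward-
    backward) Butterworth low-pass of the given order, then the force
    streams are decimated onto the marker clock.  ``cutoff_hz=None``
    skips filtering (used for noiseless synthetic round trips) but still
    decimates.  Velocities are *not* computed here; they are taken by
    central differences wherever segment states are built.
    """
    if cutoff_hz is not None:
        for fs in (trial.f_mocap, trial.f_force):
            if cutoff_hz >= fs / 2:
                raise ValueError("cutoff must be below the Nyquist rate")
    max_gap = max(1, int(round(max_gap_s * trial.f_mocap)))
    markers = {}
    for name, xyz in trial.markers.items():
        xyz = _fill_gaps(np.asarray(xyz, float), max_gap)
        if cutoff_hz is not None:
            xyz = _bidirectional_lowpass(xyz, cutoff_hz, trial.f_mocap, order)
        markers[name] = xyz
    step = int(round(trial.f_force / trial.f_mocap))
    plates = []
    for plate in (trial.seat_plate, trial.foot_plate):
        fz = np.asarray(plate.fz, float)
        cop = np.asarray(plate.cop, float)
        nan_mask = ~np.isfinite(cop).all(axis=1)
        if nan_mask.any() and not nan_mask.all():
            cop = _fill_gaps(cop, max_gap=len(cop))
        if cutoff_hz is not None:
            fz = _bidirectional_lowpass(fz, cutoff_hz, trial.f_force, order)
            if not nan_mask.all():
                cop = _bidirectional_lowpass(cop, cutoff_hz, trial.f_force, order)
        cop = np.where(nan_mask[:, None], np.nan, cop)
        n = trial.n_samples
        plates.append(ForcePlate(
            time=trial.time.copy(),
            fz=fz[::step][:n],
            cop=cop[::step][:n],
        ))
    return TrialRecording(
        time=trial.time.copy(), markers=markers,
        seat_plate=plates[0], foot_plate=plates[1],
        f_mocap=trial.f_mocap, f_force=trial.f_mocap,
        body_params=trial.body_params,
        ground_truth=trial.ground_truth, meta=dict(trial.meta),
    )


# ----------------------------------------------------------- rigid-body fit


def rigid_pose_fit(local: np.ndarray, world: np.ndarray):
    """Least-squares rigid fit of marker clouds (batch Kabsch).

    Parameters
    ----------
    local : (k, 3) marker coordinates in the segment frame (origin = COM).
    world : (T, k, 3) observed marker trajectories.

    Returns
    -------
    R : (T, 3, 3) rotations, t : (T, 3) translations with
    ``world ~= R @ local + t`` (t is the segment COM trajectory).
    """
    local = np.asarray(local, float)
    world = np.asarray(world, float)
    x0 = local.mean(axis=0)
    y0 = world.mean(axis=1)
    xc = local - x0
    yc = world - y0[:, None, :]
    h = np.einsum("ki,tkj->tij", xc, yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("tij,tjk->tik", u, vt)))
    # R = V diag(1,1,d) U^T
    vt[:, -1, :] *= d[:, None]
    r = np.einsum("tji,tkj->tik", vt, u)
    t = y0 - np.einsum("tij,j->ti", r, x0)
    return r, t


def angular_velocity_from_rotations(R: np.ndarray, dt: float) -> np.ndarray:
    """Segment angular velocity from a rotation series via finite rotations."""
    R = np.asarray(R, float)
    w = np.empty((R.shape[0], 3))
    rel = np.einsum("tij,tkj->tik", R[2:], R[:-2])  # R[t+1] R[t-1]^T
    w[1:-1] = Rotation.from_matrix(rel).as_rotvec() / (2.0 * dt)
    w[0] = Rotation.from_matrix(R[1] @ R[0].T).as_rotvec() / dt
    w[-1] = Rotation.from_matrix(R[-1] @ R[-2].T).as_rotvec() / dt
    return w


def segment_states_from_trial(trial: TrialRecording) -> dict:
    """Reconstruct every segment's state series from its marker cluster."""
    dt = 1.0 / trial.f_mocap
    states = {}
    for name, params in trial.body_params.segments.items():
        mk_names = list(params.markers)
        local = np.stack([params.markers[m] for m in mk_names])
        world = trial.marker_array(mk_names)
        R, r = rigid_pose_fit(local, world)
        v = central_difference(r, dt)
        w = angular_velocity_from_rotations(R, dt)
        J = np.einsum("tij,jk,tlk->til", R, params.inertia_local, R)
        states[name] = SegmentState(m=params.mass, r=r, v=v, J=J, w=w)
    return states
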