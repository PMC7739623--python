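"""Synthetic sit-to-stand recordings with known ground truth.

The generator emulates the mechanical structure the analysis assumes: a
planar three-link sagittal chain (shank, thigh, head-arms-trunk) rising
from a stool over two stationary feet, recorded as marker trajectories
at the motion-capture rate plus seat- and foot-plate vertical forces and
COPs at the force-plate rate.  Because the chain is prescribed
analytically, every downstream quantity -- events, whole-body state,
BOS, static and dynamic balance metrics -- has an exact reference value.

Trials come in three designs: ``clean`` (a successful repetition with
about 2 s of still sitting and standing on either side of the
transfer), ``sit_back`` (a failed attempt that partially unloads the
stool and returns to sitting), and ``foot_lift`` (a successful rise
during which four of the right foot's six markers leave the ground,
which the segmentation must reject).

Older-group effects are injected at the motion-plan level: a COM-speed
shift rescales the active-phase clock exactly, a COM-ground-projection
shift translates the chain forward, and an FPE-margin shift adjusts the
trunk pitch rate at seat-off, solved by 1-D root finding against the
subject's own unshifted plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .anthropometry import (
    GRAVITY,
    BodyParams,
    default_body_params,
    foot_com_offset,
    foot_marker_local,
)
from .bos import (
    BosTemplate,
    calibrated_foot_frames,
    default_template,
    foot_dimensions,
    scale_template,
    whole_body_bos,
)
from .kinematics import (
    SegmentState,
    WholeBodyState,
    angular_velocity_from_rotations,
    central_difference,
)
from .recording import ForcePlate, StsEvents, TrialRecording

F_MOCAP = 150.0
F_FORCE = 900.0

CHAIN_SEGMENTS = ("shank", "thigh", "hat")


@dataclass
class SyntheticCohortSpec:
    """Design of a synthetic young-vs-older cohort."""

    n_young: int = 10
    n_old: int = 8
    reps_per_subject: int = 5
    seat_height_frac: float = 0.55  # seat height / leg length (knee height)
    group_offsets: dict = field(default_factory=dict)  # metric -> shift (cm, cm/s)
    noise_sd_marker: float = 0.5  # mm
    noise_sd_force: float = 0.5  # N
    seed: int = 0

    def __post_init__(self):
        if min(self.n_young, self.n_old, self.reps_per_subject) < 1:
            raise ValueError("cohort counts must be >= 1")
        if self.noise_sd_marker < 0 or self.noise_sd_force < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_old

    def group_of(self, subject_index: int) -> str:
        if not 0 <= subject_index < self.n_subjects:
            raise ValueError("subject index out of range")
        return "young" if subject_index < self.n_young else "old"


def _s5(u):
    """Quintic smoothstep on [0, 1] (zero velocity/acceleration at ends)."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def _prog(u, start, dur):
    return _s5((u - start) / dur)


@dataclass
class MotionPlan:
    """Fully-specified joint trajectory plan of one trial."""

    body: BodyParams
    trial_type: str = "clean"
    t_sit: float = 2.0
    stand_dur: float = 2.0
    k: float = 1.0  # active-phase time scale (>1 is slower)
    # schedule within the active phase, in unscaled seconds
    lean_start: float = 0.30
    lean_dur: float = 1.75
    rise_start: float = 0.45
    rise_dur: float = 2.05
    unload_start: float = 0.73
    unload_dur: float = 0.58
    extend_start: float = 1.75
    extend_dur: float = 1.15
    active_dur: float = 2.9
    # postures (rad): segment pitch from vertical, forward positive
    alpha_s_sit: float = math.radians(18.0)
    alpha_s_stand: float = math.radians(2.0)
    alpha_t_sit: float = math.radians(-95.0)
    alpha_t_stand: float = math.radians(2.0)
    alpha_h_sit: float = math.radians(15.0)
    alpha_h_stand: float = math.radians(3.0)
    lean_amp: float = math.radians(25.0)
    pitch_boost: float = 0.0  # extra trunk pitch ramped through seat-off (rad)
    # geometry
    ankle_height: float = 0.08
    foot_sep: float = 0.10  # lateral ankle offset from the midline
    chain_shift_y: float = 0.0  # whole-chain forward translation
    yaw_amp: float = 0.0  # optional yaw rotation injected during the rise
    seat_share: float = 0.65  # fraction of body weight on the stool while seated
    seat_taper_slope: float = 165.0  # N/s: end slope of the unloading ramp
    cop_y_sit: float = -0.04
    # sit-back shaping
    sitback_thigh: float = math.radians(-78.0)
    sitback_unload: float = 0.7  # fraction of the seat load shed at the peak

    @property
    def t_seatoff(self) -> float:
        return self.t_sit + (self.unload_start + self.unload_dur) * self.k

    @property
    def t_active_end(self) -> float:
        return self.t_sit + self.active_dur * self.k

    @property
    def duration(self) -> float:
        return self.t_active_end + self.stand_dur

    def phase(self, t):
        return (np.asarray(t, float) - self.t_sit) / self.k


def _plan_angles(plan: MotionPlan, t: np.ndarray):
    """Segment pitch angles (shank, thigh, trunk) at times ``t``."""
    u = plan.phase(t)
    if plan.trial_type == "sit_back":
        # a vigorous but aborted attempt: brief partial hip rise, reduced
        # trunk lean (so the COM height excursion is a short-lived bump,
        # never a sustained standing-height plateau), return to sitting
        bump_dur = 0.35 * plan.rise_dur
        up = _prog(u, plan.rise_start, bump_dur)
        down = _prog(u, plan.rise_start + bump_dur, bump_dur)
        bump = up - down
        a_s = np.full_like(u, plan.alpha_s_sit)
        a_t = plan.alpha_t_sit + (plan.sitback_thigh - plan.alpha_t_sit) * bump
        lean = _prog(u, plan.lean_start, plan.lean_dur) - \
            _prog(u, plan.extend_start, plan.extend_dur)
        a_h = plan.alpha_h_sit + 0.3 * plan.lean_amp * lean
        return a_s, a_t, a_h
    rise = _prog(u, plan.rise_start, plan.rise_dur)
    a_s = plan.alpha_s_sit + (plan.alpha_s_stand - plan.alpha_s_sit) * rise
    a_t = plan.alpha_t_sit + (plan.alpha_t_stand - plan.alpha_t_sit) * rise
    ext = _prog(u, plan.extend_start, plan.extend_dur)
    a_h = plan.alpha_h_sit + plan.lean_amp * _prog(u, plan.lean_start, plan.lean_dur)
    a_h = a_h + (plan.alpha_h_stand - plan.alpha_h_sit - plan.lean_amp) * ext
    if plan.pitch_boost:
        # sigmoid ramp whose rate peaks at the designed seat-off; faded
        # out during trunk extension so the standing posture is unchanged
        u_so = plan.unload_start + plan.unload_dur
        half = 0.35
        a_h = a_h + plan.pitch_boost * _s5((u - (u_so - half)) / (2 * half)) * (1.0 - ext)
    return a_s, a_t, a_h


def _dir(alpha):
    """Unit vector of a segment pitched ``alpha`` forward from vertical."""
    alpha = np.asarray(alpha, float)
    z = np.zeros_like(alpha)
    return np.stack([z, np.sin(alpha), np.cos(alpha)], axis=-1)


def _pitch_matrices(alpha):
    """World rotations mapping segment-local z onto the pitched axis."""
    return Rotation.from_euler("x", -np.atleast_1d(alpha)[:, None]).as_matrix()


def _chain_geometry(plan: MotionPlan, t: np.ndarray):
    """COM positions and rotations of the three chain segments."""
    segs = plan.body.segments
    Ls, Lt, Lh = (segs[n].length for n in CHAIN_SEGMENTS)
    cs, ct, ch = (segs[n].com_frac for n in CHAIN_SEGMENTS)
    a_s, a_t, a_h = _plan_angles(plan, t)
    ankle = np.array([0.0, plan.chain_shift_y, plan.ankle_height])
    knee = ankle + Ls * _dir(a_s)
    hip = knee + Lt * _dir(a_t)
    com = {
        "shank": ankle + (1.0 - cs) * Ls * _dir(a_s),
        "thigh": knee + (1.0 - ct) * Lt * _dir(a_t),
        "hat": hip + ch * Lh * _dir(a_h),
    }
    rot = {
        "shank": _pitch_matrices(a_s),
        "thigh": _pitch_matrices(a_t),
        "hat": _pitch_matrices(a_h),
    }
    if plan.yaw_amp != 0.0:
        u = plan.phase(t)
        psi = plan.yaw_amp * _prog(u, plan.rise_start, plan.rise_dur)
        Rz = Rotation.from_euler("z", np.atleast_1d(psi)).as_matrix()
        for name in com:
            rel = com[name] - ankle
            com[name] = ankle + np.einsum("...ij,...j->...i", Rz, rel)
            rot[name] = np.einsum("...ij,...jk->...ik", Rz, rot[name])
    return com, rot


def _foot_statics(plan: MotionPlan):
    """Static world positions of foot markers and foot segment COMs."""
    markers = {}
    coms = {}
    for side, sign in (("left", -1.0), ("right", 1.0)):
        origin = np.array([sign * plan.foot_sep, 0.0, 0.0])
        prefix = side[0].upper()
        for name, loc in foot_marker_local(side).items():
            markers[prefix + name] = origin + loc
        coms[side] = origin + foot_com_offset(side)
    return markers, coms


def _chain_segment_states(plan: MotionPlan, t: np.ndarray) -> dict:
    """Exact segment states of the full body at the sampled times."""
    dt = float(t[1] - t[0])
    com, rot = _chain_geometry(plan, t)
    _, foot_coms = _foot_statics(plan)
    states = {}
    for name in CHAIN_SEGMENTS:
        params = plan.body.segments[name]
        R = rot[name]
        r = com[name]
        states[name] = SegmentState(
            m=params.mass,
            r=r,
            v=central_difference(r, dt),
            J=np.einsum("tij,jk,tlk->til", R, params.inertia_local, R),
            w=angular_velocity_from_rotations(R, dt),
        )
    T = t.shape[0]
    for side in ("left", "right"):
        params = plan.body.segments[f"foot_{side}"]
        r = np.broadcast_to(foot_coms[side], (T, 3)).copy()
        states[f"foot_{side}"] = SegmentState(
            m=params.mass,
            r=r,
            v=np.zeros((T, 3)),
            J=np.broadcast_to(params.inertia_local, (T, 3, 3)).copy(),
            w=np.zeros((T, 3)),
        )
    return states


def _seat_force(plan: MotionPlan, t: np.ndarray) -> np.ndarray:
    """Seat-plate vertical force: smooth taper reaching exactly zero.

    The taper blends a quintic smoothstep with a small linear ramp.
    The smoothstep alone would approach zero with vanishing slope,
    putting the 1 N seat-off detection threshold many samples before
    the designed zero-force instant; the linear share keeps a fixed,
    modest end slope so the threshold is crossed within a fraction of a
    sample of the true event regardless of body weight and pace, while
    the slope-change at the corner stays small enough that the
    zero-phase low-pass filter shifts the crossing by well under one
    sample.
    """
    u = plan.phase(t)
    base = plan.seat_share * plan.body.weight
    q = np.clip((u - plan.unload_start) / plan.unload_dur, 0.0, 1.0)
    if plan.trial_type == "sit_back":
        up = _s5(q)
        down = _prog(u, plan.unload_start + plan.unload_dur, plan.unload_dur)
        return base * (1.0 - plan.sitback_unload * (up - down))
    lam = float(np.clip(plan.seat_taper_slope * plan.unload_dur * plan.k / base,
                        0.05, 0.6))
    return base * ((1.0 - lam) * (1.0 - _s5(q)) + lam * (1.0 - q))


def _standing_com_y(plan: MotionPlan) -> float:
    com, _ = _chain_geometry(plan, np.asarray([plan.duration]))
    _, foot_coms = _foot_statics(plan)
    m_tot = plan.body.total_mass
    y = 0.0
    for name in CHAIN_SEGMENTS:
        y += plan.body.segments[name].mass * com[name][0, 1]
    for side in ("left", "right"):
        y += plan.body.segments[f"foot_{side}"].mass * foot_coms[side][1]
    return y / m_tot


def _foot_cop(plan: MotionPlan, t: np.ndarray) -> np.ndarray:
    """Planned foot-plate COP: from under the heels to under the COM."""
    u = plan.phase(t)
    y_end = plan.cop_y_sit if plan.trial_type == "sit_back" else _standing_com_y(plan)
    y = plan.cop_y_sit + (y_end - plan.cop_y_sit) * _prog(u, plan.rise_start, plan.rise_dur)
    return np.column_stack([np.zeros_like(y), y])


# ----------------------------------------------------------- plan assembly


def _subject_body(rng: np.random.Generator) -> BodyParams:
    mass = float(np.clip(rng.normal(75.0, 8.0), 50.0, 110.0))
    stature = float(np.clip(rng.normal(1.72, 0.06), 1.50, 1.95))
    return default_body_params(total_mass=mass, stature=stature)


#: cohort reference COM speed at seat-off (m/s); subjects are solved to
#: this anchor plus their individual delta, so body size does not leak
#: into the speed spread
SEATOFF_SPEED_REF = 0.45

#: between-subject SDs of the seat-off targets (m, m/s, m): a controlled
#: cohort with spreads at the tight end of what such groups exhibit, so
#: designed group effects of a few cm (cm/s) are cleanly detectable at
#: 8-10 subjects per group
SUBJECT_SD = {"d_bg": 0.012, "com_speed": 0.03, "d_bf": 0.007}


def _base_plan(spec: SyntheticCohortSpec, subject_index: int, rep_index: int,
               trial_type: str) -> MotionPlan:
    s_rng = np.random.default_rng([spec.seed, 1000 + subject_index])
    body = _subject_body(s_rng)
    r_rng = np.random.default_rng([spec.seed, 1000 + subject_index, 10 + rep_index])
    k_rep = float(np.clip(1.0 + r_rng.normal(0.0, 0.015), 0.9, 1.1))
    y_rep = float(r_rng.normal(0.0, 0.003))
    lean_rep = float(r_rng.normal(0.0, math.radians(0.6)))
    return MotionPlan(
        body=body,
        trial_type=trial_type,
        k=k_rep,
        chain_shift_y=y_rep * body.total_mass /
        sum(body.segments[n].mass for n in CHAIN_SEGMENTS),
        lean_amp=math.radians(25.0) + lean_rep,
    )


def _subject_target_deltas(spec: SyntheticCohortSpec, subject_index: int) -> dict:
    """Per-subject shifts of the seat-off targets (plus group offsets)."""
    s_rng = np.random.default_rng([spec.seed, 5000 + subject_index])
    deltas = {name: float(s_rng.normal(0.0, sd)) for name, sd in SUBJECT_SD.items()}
    if spec.group_of(subject_index) == "old":
        for name in deltas:
            deltas[name] += spec.group_offsets.get(name, 0.0) / 100.0  # cm -> m
    return deltas


def _seatoff_probe(plan: MotionPlan):
    """COM speed and FPE forward offset (h tan phi) at the designed seat-off."""
    from .fpe import angular_momentum_about_gp, project_state, solve_fpe, travel_frame

    dt = 1.0 / F_MOCAP
    t_so = plan.t_seatoff
    t = t_so + dt * np.arange(-2, 3)
    states = _chain_segment_states(plan, t)
    wb = WholeBodyState.from_segments(states.values())
    wb.mass = plan.body.total_mass
    i = 2
    speed = float(np.linalg.norm(wb.v_C[i]))
    H_G = angular_momentum_about_gp(wb)
    frame = travel_frame(H_G, v_C=wb.v_C)
    inp = project_state(wb, frame)
    sol = solve_fpe(inp)
    h_tan_phi = float(wb.h[i] * math.tan(sol.phi[i]))
    return speed, h_tan_phi


def _apply_target_deltas(plan: MotionPlan, deltas: dict) -> MotionPlan:
    """Shift the plan's seat-off targets by the given amounts (SI units).

    The COM-speed shift rescales the active-phase clock exactly; the
    FPE forward offset (h tan phi) is matched by solving for the trunk
    pitch-rate boost; the COM ground-projection shift is a whole-chain
    translation applied last (it moves G and the FPE point equally).
    """
    d_speed = deltas.get("com_speed", 0.0)
    d_bg = deltas.get("d_bg", 0.0)
    d_bf = deltas.get("d_bf", 0.0)
    v0, htan0 = _seatoff_probe(plan)
    target_v = SEATOFF_SPEED_REF + d_speed
    target_h = htan0 + (d_bf - d_bg)
    if target_v <= 0.05:
        raise ValueError("speed offset would stall the transfer")

    def with_speed(p):
        # the active-phase clock scales speed almost exactly inversely;
        # two fixed-point steps reach sub-mm/s accuracy
        for _ in range(2):
            v_cur, _ = _seatoff_probe(p)
            p = replace(p, k=p.k * v_cur / target_v)
        return p

    if d_bf or d_bg:
        # nested solve: for each candidate pitch boost first hit the speed
        # target, then drive the FPE forward offset to its target
        def err(boost):
            return _seatoff_probe(with_speed(replace(plan, pitch_boost=boost)))[1] \
                - target_h

        lo, hi = math.radians(-45.0), math.radians(45.0)
        e_lo, e_hi = err(lo), err(hi)
        if e_lo * e_hi <= 0:
            boost = brentq(err, lo, hi, xtol=1e-4)
        else:
            # target just outside the reachable band: clamp to the nearer
            # end (best-effort; the residual shift is small)
            boost = lo if abs(e_lo) < abs(e_hi) else hi
        plan = replace(plan, pitch_boost=boost)
    plan = with_speed(plan)
    if d_bg:
        m_chain = sum(plan.body.segments[n].mass for n in CHAIN_SEGMENTS)
        plan = replace(plan, chain_shift_y=plan.chain_shift_y +
                       d_bg * plan.body.total_mass / m_chain)
    return plan


# ------------------------------------------------------------ trial assembly


def _emit_recording(plan: MotionPlan, spec: SyntheticCohortSpec,
                    noise_rng: np.random.Generator | None,
                    foot_lift: bool = False) -> TrialRecording:
    n150 = int(round(plan.duration * F_MOCAP)) + 1
    t150 = np.arange(n150) / F_MOCAP
    t900 = np.arange(6 * (n150 - 1) + 1) / F_FORCE

    com, rot = _chain_geometry(plan, t150)
    foot_markers, _ = _foot_statics(plan)
    markers = {}
    for name in CHAIN_SEGMENTS:
        params = plan.body.segments[name]
        for mk, loc in params.markers.items():
            markers[mk] = com[name] + np.einsum("tij,j->ti", rot[name], loc)
    for mk, pos in foot_markers.items():
        markers[mk] = np.broadcast_to(pos, (n150, 3)).copy()
    if foot_lift:
        u = plan.phase(t150)
        up = _prog(u, plan.rise_start, plan.rise_dur * 0.5)
        down = _prog(u, plan.rise_start + plan.rise_dur * 0.5, plan.rise_dur * 0.5)
        bump = 0.020 * (up - down)
        for mk in ("RFAL", "RTAM", "RFM1", "RFM5"):
            markers[mk] = markers[mk].copy()
            markers[mk][:, 2] += bump

    seat_fz = _seat_force(plan, t900)
    foot_fz = plan.body.weight - seat_fz
    seat_cop = np.broadcast_to(
        np.array([0.0, plan.chain_shift_y - 0.33]), (t900.shape[0], 2)).copy()
    seat_cop[seat_fz < 5.0] = np.nan
    foot_cop = _foot_cop(plan, t900)

    if noise_rng is not None and (spec.noise_sd_marker or spec.noise_sd_force):
        sd_m = spec.noise_sd_marker / 1000.0
        for mk in markers:
            markers[mk] = markers[mk] + noise_rng.normal(0.0, sd_m, markers[mk].shape)
        seat_fz = seat_fz + noise_rng.normal(0.0, spec.noise_sd_force, seat_fz.shape)
        foot_fz = foot_fz + noise_rng.normal(0.0, spec.noise_sd_force, foot_fz.shape)
        foot_cop = foot_cop + noise_rng.normal(0.0, sd_m, foot_cop.shape)

    return TrialRecording(
        time=t150,
        markers=markers,
        seat_plate=ForcePlate(time=t900, fz=seat_fz, cop=seat_cop),
        foot_plate=ForcePlate(time=t900, fz=foot_fz, cop=foot_cop),
        f_mocap=F_MOCAP,
        f_force=F_FORCE,
        body_params=plan.body,
    )


def _true_events(plan: MotionPlan, t150: np.ndarray) -> StsEvents:
    """Designed event times evaluated on the noiseless plan."""
    states = _chain_segment_states(plan, t150)
    r, v = _weighted_com(plan, states)
    speed = np.linalg.norm(v, axis=1)
    moving = np.flatnonzero((t150 >= plan.t_sit) & (speed >= 0.01))
    t_init = float(t150[moving[0]]) if moving.size else np.nan
    h_stand = r[-1, 2]
    after = t150 >= plan.t_seatoff
    ok = np.flatnonzero(after & (np.abs(r[:, 2] - h_stand) <= 0.01)
                        & (np.abs(v[:, 2]) < 0.01))
    t_stance = float(t150[ok[0]]) if ok.size else np.nan
    return StsEvents(t_init=t_init, t_seatoff=plan.t_seatoff,
                     t_stance=t_stance, accepted=True)


def _weighted_com(plan: MotionPlan, states: dict):
    m = np.array([s.m for s in states.values()])
    r = np.stack([s.r for s in states.values()])
    v = np.stack([s.v for s in states.values()])
    w = m / m.sum()
    return np.einsum("s,sti->ti", w, r), np.einsum("s,sti->ti", w, v)


def _ground_truth(plan: MotionPlan, trial: TrialRecording,
                  template: BosTemplate, full: bool) -> dict:
    from .pipeline import balance_metric_series

    t150 = trial.time
    gt: dict = {"events": _true_events(plan, t150),
                "t_seatoff": plan.t_seatoff}
    states = _chain_segment_states(plan, t150)
    wb = WholeBodyState.from_segments(states.values())
    wb.mass = plan.body.total_mass
    gt["state"] = wb
    if full:
        # exact (noise-free) marker means define the foot frames/BOS
        exact = _emit_recording(plan, SyntheticCohortSpec(noise_sd_marker=0.0,
                                                          noise_sd_force=0.0),
                                None)
        frames = calibrated_foot_frames(exact)
        polys = []
        for side in ("left", "right"):
            mks = {name: exact.markers[side[0].upper() + name][0]
                   for name in ("FAL", "TAM", "FM1", "FM2", "FM5", "FCC")}
            w, ell = foot_dimensions(mks, side)
            polys.append(scale_template(template, w, ell, frames[side]))
        bos = whole_body_bos(*polys)
        cop150 = _foot_cop(plan, t150)
        gt["bos"] = bos
        gt["metrics"] = balance_metric_series(wb, bos, cop150, plan.body.total_mass)
    return gt


# ------------------------------------------------------------------- public


def generate_sts_trial(
    spec: SyntheticCohortSpec,
    subject_index: int,
    rep_index: int,
    trial_type: str = "clean",
    template: BosTemplate | None = None,
    ground_truth: str = "full",
) -> TrialRecording:
    """Generate one sit-to-stand trial for a cohort subject.

    ``trial_type`` is ``"clean"``, ``"sit_back"`` or ``"foot_lift"``;
    ``ground_truth`` selects ``"full"`` (events + state + metric series),
    ``"events"`` or ``"none"``.
    """
    if trial_type not in ("clean", "sit_back", "foot_lift"):
        raise ValueError(f"unknown trial type {trial_type!r}")
    group = spec.group_of(subject_index)
    plan = _base_plan(spec, subject_index, rep_index,
                      "sit_back" if trial_type == "sit_back" else "clean")
    if plan.trial_type == "clean":
        plan = _apply_target_deltas(plan, _subject_target_deltas(spec, subject_index))
    if not plan.t_sit < plan.t_seatoff < plan.duration:
        raise ValueError("designed seat-off falls outside the trial window")
    noise_rng = np.random.default_rng([spec.seed, 2, subject_index, rep_index])
    trial = _emit_recording(plan, spec, noise_rng, foot_lift=(trial_type == "foot_lift"))
    trial.meta = {"subject": subject_index, "rep": rep_index, "group": group,
                  "trial_type": trial_type}
    if ground_truth != "none" and trial_type != "foot_lift":
        template = template or default_template()
        trial.ground_truth = _ground_truth(plan, trial, template,
                                           full=(ground_truth == "full"
                                                 and trial_type == "clean"))
    return trial


def generate_quiet_standing(
    spec: SyntheticCohortSpec,
    subject_index: int,
    duration_s: float = 10.0,
    sway_sd: float = 0.005,
    cop_wander_sd: float = 0.002,
) -> TrialRecording:
    """Quiet-standing trial: band-limited sway about the standing pose.

    The ankle-strategy sway angle series is low-pass noise (1 Hz)
    rescaled so the horizontal COM excursion has *exactly* the
    configured standard deviation; different subjects therefore differ
    in realization but share the envelope parameters.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    spec.group_of(subject_index)
    s_rng = np.random.default_rng([spec.seed, 1000 + subject_index])
    body = _subject_body(s_rng)
    plan = MotionPlan(body=body, t_sit=0.0, stand_dur=duration_s, active_dur=0.0,
                      k=1.0)
    n150 = int(round(duration_s * F_MOCAP))
    t150 = np.arange(n150) / F_MOCAP
    t900 = np.arange(6 * n150) / F_FORCE

    # standing chain pose (no active phase: clamp angles at their stand values)
    stand_plan = replace(plan, t_sit=-10.0, active_dur=0.0)
    com, rot = _chain_geometry(stand_plan, t150)
    rng = np.random.default_rng([spec.seed, 3, subject_index])

    def band_limited(n, fs, target_sd, rng):
        x = rng.normal(size=n)
        sos = butter(2, 1.0, btype="low", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
        x = x - x.mean()
        sd = x.std()
        return x * (target_sd / sd) if sd > 0 and target_sd > 0 else np.zeros(n)

    ankle = np.array([0.0, 0.0, plan.ankle_height])
    # lever arm of the whole-body COM about the ankle sway axis (only the
    # chain sways; the feet stay put)
    h_lever = sum(
        body.segments[n].mass * (float(np.mean(com[n][:, 2])) - plan.ankle_height)
        for n in CHAIN_SEGMENTS) / body.total_mass
    amp = sway_sd / h_lever
    pitch = band_limited(n150, F_MOCAP, amp, rng)
    roll = band_limited(n150, F_MOCAP, 0.6 * amp, rng)
    sway = Rotation.from_euler("yx", np.column_stack([roll, -pitch])).as_matrix()
    markers = {}
    for name in CHAIN_SEGMENTS:
        params = plan.body.segments[name]
        c = ankle + np.einsum("tij,tj->ti", sway, com[name] - ankle)
        R = np.einsum("tij,tjk->tik", sway, rot[name])
        com[name], rot[name] = c, R
        for mk, loc in params.markers.items():
            markers[mk] = c + np.einsum("tij,j->ti", R, loc)
    foot_markers, _ = _foot_statics(plan)
    for mk, pos in foot_markers.items():
        markers[mk] = np.broadcast_to(pos, (n150, 3)).copy()

    states = _chain_segment_states_from_series(plan, com, rot, n150)
    wb = WholeBodyState.from_segments(states.values())
    wb.mass = body.total_mass

    bias = np.array([0.004, 0.006])
    wander = np.column_stack([
        band_limited(6 * n150, F_FORCE, cop_wander_sd, rng),
        band_limited(6 * n150, F_FORCE, cop_wander_sd, rng)])
    com_gp_900 = np.repeat(wb.com_gp, 6, axis=0)[:6 * n150]
    foot_cop = com_gp_900 + bias + wander
    foot_fz = np.full(6 * n150, body.weight)
    seat_fz = np.zeros(6 * n150)
    seat_cop = np.full((6 * n150, 2), np.nan)

    noise_rng = np.random.default_rng([spec.seed, 4, subject_index])
    if spec.noise_sd_marker or spec.noise_sd_force:
        sd_m = spec.noise_sd_marker / 1000.0
        for mk in markers:
            markers[mk] = markers[mk] + noise_rng.normal(0.0, sd_m, markers[mk].shape)
        foot_fz = foot_fz + noise_rng.normal(0.0, spec.noise_sd_force, foot_fz.shape)
        seat_fz = seat_fz + noise_rng.normal(0.0, spec.noise_sd_force, seat_fz.shape)

    trial = TrialRecording(
        time=t150, markers=markers,
        seat_plate=ForcePlate(time=t900, fz=seat_fz, cop=seat_cop),
        foot_plate=ForcePlate(time=t900, fz=foot_fz, cop=foot_cop),
        f_mocap=F_MOCAP, f_force=F_FORCE, body_params=body,
        ground_truth={"state": wb, "sway_sd": sway_sd},
        meta={"subject": subject_index, "kind": "quiet_standing"},
    )
    return trial


def _chain_segment_states_from_series(plan, com, rot, n):
    dt = 1.0 / F_MOCAP
    _, foot_coms = _foot_statics(plan)
    states = {}
    for name in CHAIN_SEGMENTS:
        params = plan.body.segments[name]
        R = rot[name]
        states[name] = SegmentState(
            m=params.mass, r=com[name],
            v=central_difference(com[name], dt),
            J=np.einsum("tij,jk,tlk->til", R, params.inertia_local, R),
            w=angular_velocity_from_rotations(R, dt),
        )
    for side in ("left", "right"):
        params = plan.body.segments[f"foot_{side}"]
        states[f"foot_{side}"] = SegmentState(
            m=params.mass,
            r=np.broadcast_to(foot_coms[side], (n, 3)).copy(),
            v=np.zeros((n, 3)),
            J=np.broadcast_to(params.inertia_local, (n, 3, 3)).copy(),
            w=np.zeros((n, 3)),
        )
    return states


#: true functional region in left-foot normalized coordinates
TRUE_REGION = np.array([
    (-0.42, -0.12), (-0.50, 0.25), (-0.35, 0.62), (0.05, 0.70),
    (0.38, 0.48), (0.45, 0.05), (0.15, -0.18), (-0.15, -0.20),
])


def generate_cop_excursion_trial(
    foot_length: float = 0.25,
    foot_width: float = 0.09,
    seed: int = 0,
    total_mass: float = 75.0,
    phase_s: float = 20.0,
    n_turns: int = 14,
) -> TrialRecording:
    """COP-excursion recording used to build the functional BOS template.

    The COP spirals outward inside a known convex region attached to
    each foot, one foot loaded at a time with ~62% body weight (single-
    leg stance); a mid-phase segment tilts the loaded foot past the
    flatness allowance while the COP strays outside the region, which
    the template builder must filter out.
    """
    if foot_length <= 0 or foot_width <= 0:
        raise ValueError("foot dimensions must be positive")
    body = default_body_params(total_mass=total_mass)
    rng = np.random.default_rng(seed)
    sx, sy = foot_width / 0.09, foot_length / 0.25
    n_phase = int(round(phase_s * F_MOCAP))
    n150 = 2 * n_phase
    t150 = np.arange(n150) / F_MOCAP

    from shapely.geometry import Polygon as _Poly
    region = _Poly(TRUE_REGION)
    from .bos import _hull_vertices, _ray_radii

    verts = _hull_vertices(TRUE_REGION)
    centroid = np.asarray(region.centroid.coords[0])

    def spiral(n, rng):
        tt = np.linspace(0.0, 1.0, n)
        theta = 2.0 * np.pi * n_turns * tt + rng.uniform(0, 2 * np.pi)
        rho = np.minimum(1.0, tt / 0.85)  # outward sweep, final turns on boundary
        rmax = _ray_radii(verts, centroid, np.mod(theta, 2 * np.pi))
        pts = centroid + (rho * rmax)[:, None] * \
            np.column_stack([np.cos(theta), np.sin(theta)])
        return pts  # normalized left-foot coords

    markers = {}
    foot_markers, _ = _foot_statics(MotionPlan(body=body))
    for mk, pos in foot_markers.items():
        markers[mk] = np.broadcast_to(pos, (n150, 3)).copy()
    # scale feet to the requested dimensions
    for mk in markers:
        origin = np.array([-0.10 if mk.startswith("L") else 0.10, 0.0, 0.0])
        rel = markers[mk] - origin
        rel[:, 0] *= sx
        rel[:, 1] *= sy
        markers[mk] = origin + rel

    # lay the COP down in the same measured, calibrated foot frames the
    # template builder recovers, so the known region is scaled exactly
    # to each foot as seen by the analysis
    from .bos import calibrate_foot_frame, foot_frame as _foot_frame

    frames, dims = {}, {}
    for side in ("left", "right"):
        prefix = side[0].upper()
        mks = {name: markers[prefix + name][0] for name in
               ("FAL", "TAM", "FM1", "FM2", "FM5", "FCC")}
        frames[side] = calibrate_foot_frame(_foot_frame(mks, side))
        from .bos import foot_dimensions as _fd
        dims[side] = _fd(mks, side)

    fz = np.full(n150, 0.62 * body.weight)
    cop = np.zeros((n150, 2))
    # roll about the foot's long axis large enough to violate flatness
    for phase, side in enumerate(("left", "right")):
        sl = slice(phase * n_phase, (phase + 1) * n_phase)
        pts = spiral(n_phase, rng)
        w, ell = dims[side]
        fr = frames[side]
        sign = 1.0 if side == "left" else -1.0
        local = np.column_stack([pts[:, 0] * w * sign, pts[:, 1] * ell])
        cop[sl] = (fr.origin[:2]
                   + local[:, :1] * fr.x[:2] + local[:, 1:] * fr.y[:2])
        # tilt segment: roll past the allowance, COP beyond the toes
        flat_break = math.asin(0.025 / ell)
        i0 = phase * n_phase + n_phase // 2
        i1 = i0 + n_phase // 10
        tilt_idx = slice(i0, i1)
        prefix = side[0].upper()
        heel = markers[prefix + "FCC"][0]
        Ry = Rotation.from_euler("y", flat_break).as_matrix()
        for name in ("FAL", "TAM", "FM1", "FM2", "FM5", "FCC"):
            mk = prefix + name
            rel = markers[mk][tilt_idx] - heel
            markers[mk][tilt_idx] = heel + rel @ Ry.T
        cop[tilt_idx] = (fr.origin[:2] + 1.4 * ell * fr.y[:2])
        # the roll on/off transitions are accompanied by unloading below
        # half body weight (as when a person rolls onto the toes)
        half = int(0.2 * F_MOCAP)
        for edge in (i0, i1):
            fz[max(0, edge - half):edge + half] = 0.3 * body.weight
    # brief unweighted gap between phases
    gap = slice(n_phase - n_phase // 20, n_phase + n_phase // 20)
    fz[gap] = 0.3 * body.weight

    t900 = np.arange(6 * n150) / F_FORCE
    rep = lambda a: np.repeat(a, 6, axis=0)
    trial = TrialRecording(
        time=t150, markers=markers,
        seat_plate=ForcePlate(time=t900, fz=np.zeros(6 * n150),
                              cop=np.full((6 * n150, 2), np.nan)),
        foot_plate=ForcePlate(time=t900, fz=rep(fz), cop=rep(cop)),
        f_mocap=F_MOCAP, f_force=F_FORCE, body_params=body,
        ground_truth={"region_vertices": verts,
                      "region_area": float(region.area)},
        meta={"kind": "cop_excursion"},
    )
    return trial
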