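"""Foot placement estimator (FPE) and the dynamic balance metrics.

The FPE is the ground point where the centre of pressure must be placed
so that an inverted-pendulum abstraction of the body -- a single rigid
body with the participant's mass m, COM height h, inertia J about the
turning axis, planar velocity (v_s1, v_z1) and angular velocity w1 --
passively rotates up into a statically balanced standing pose.  The
contact angle phi (leg inclination from vertical) satisfies f(phi) = 0
with

    f = (m h (v_s1 c + v_z1 s) c + J w1 c^2)^2 / (m h^2 + J c^2)
        + 2 m g h c (c - 1),                       c = cos(phi), s = sin(phi)

derived from angular-momentum conservation at contact and the energy
balance 1/2 (J + m l^2) w2^2 = m g (l - h), with leg length l = h/c.
The FPE ground point is r_F = r_G + (h tan phi) s-hat.

The planar state is obtained by projecting the whole-body state onto a
vertical travel plane: t-hat lies along the horizontal component of the
angular momentum about the COM ground projection (H_G), and
s-hat = t-hat x z-hat is the straight-step direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import GRAVITY
from .bos import BosPolygon, signed_distance
from .kinematics import WholeBodyState

ZHAT = np.array([0.0, 0.0, 1.0])


# ------------------------------------------------------------- travel frame


@dataclass
class TravelFrame:
    """Horizontal travel axes: s-hat (straight step), t-hat (turning)."""

    s: np.ndarray  # (..., 3)
    t: np.ndarray  # (..., 3)
    valid: np.ndarray | bool = True


def angular_momentum_about_gp(state: WholeBodyState) -> np.ndarray:
    """H_G = H_C + (r_C - r_G) x m v_C with r_G the COM ground projection."""
    m = _total_mass_of(state)
    lever = np.zeros_like(state.r_C)
    lever[..., 2] = state.h
    return state.H_C + np.cross(lever, m * state.v_C)


def _total_mass_of(state: WholeBodyState) -> float:
    m = getattr(state, "mass", None)
    if m is None:
        raise ValueError("WholeBodyState needs a 'mass' attribute for H_G")
    return m


def travel_frame(
    H_G: np.ndarray,
    v_C: np.ndarray | None = None,
    h_threshold: float = 1e-3,
    v_threshold: float = 1e-3,
) -> TravelFrame:
    """Travel axes from the horizontal angular momentum, with fallbacks.

    Where the horizontal part of H_G is too small to define a heading,
    the horizontal COM velocity is used instead (mapped to s-hat); where
    both are degenerate the last valid frame is carried forward.  Leading
    samples with no usable heading at all are flagged invalid.
    """
    H = np.atleast_2d(np.asarray(H_G, float))
    T = H.shape[0]
    s = np.full((T, 3), np.nan)
    t = np.full((T, 3), np.nan)
    Hh = H.copy()
    Hh[:, 2] = 0.0
    nH = np.linalg.norm(Hh, axis=1)
    use_h = nH > h_threshold
    t[use_h] = Hh[use_h] / nH[use_h, None]
    if v_C is not None:
        v = np.atleast_2d(np.asarray(v_C, float)).copy()
        v[:, 2] = 0.0
        nv = np.linalg.norm(v, axis=1)
        use_v = (~use_h) & (nv > v_threshold)
        sv = v[use_v] / nv[use_v, None]
        t[use_v] = np.cross(ZHAT, sv)  # so that s = t x z recovers sv
    defined = np.isfinite(t).all(axis=1)
    if defined.any():
        # forward-fill the last defined frame
        idx = np.where(defined, np.arange(T), -1)
        idx = np.maximum.accumulate(idx)
        ok = idx >= 0
        t[ok] = t[idx[ok]]
    s = np.cross(t, ZHAT)
    valid = np.isfinite(t).all(axis=1)
    if np.asarray(H_G).ndim == 1:
        return TravelFrame(s=s[0], t=t[0], valid=bool(valid[0]))
    return TravelFrame(s=s, t=t, valid=valid)


# ---------------------------------------------------------------- projection


@dataclass
class FpePlanarInput:
    """Planar single-body state in the s-z travel plane."""

    m: float | np.ndarray
    h: np.ndarray
    v_s1: np.ndarray
    v_z1: np.ndarray
    w1: np.ndarray
    J: np.ndarray
    g: float = GRAVITY


def project_state(state: WholeBodyState, frame: TravelFrame, mass: float | None = None
                  ) -> FpePlanarInput:
    """Project the whole-body state onto the s-z plane."""
    m = mass if mass is not None else _total_mass_of(state)
    h = state.h
    if np.any(h <= 0):
        raise ValueError("COM height must be positive")
    v_s1 = np.einsum("...i,...i->...", state.v_C, frame.s)
    v_z1 = state.v_C[..., 2]
    w1 = np.einsum("...i,...i->...", state.w_avg, frame.t)
    J = np.einsum("...i,...ij,...j->...", frame.t, state.J_C, frame.t)
    return FpePlanarInput(m=m, h=h, v_s1=v_s1, v_z1=v_z1, w1=w1, J=J)


# -------------------------------------------------------------------- solver


def fpe_residual(phi, m, h, v_s1, v_z1, w1, J, g=GRAVITY):
    """The balance residual f(phi); zero at the FPE contact angle."""
    c = np.cos(phi)
    s = np.sin(phi)
    u = v_s1 * c + v_z1 * s
    n = m * h * u * c + J * w1 * c * c
    d = m * h * h + J * c * c
    return n * n / d + 2.0 * m * g * h * c * (c - 1.0)


def _fpe_residual_grad(phi, m, h, v_s1, v_z1, w1, J, g=GRAVITY):
    """Analytic d f / d phi."""
    c = np.cos(phi)
    s = np.sin(phi)
    u = v_s1 * c + v_z1 * s
    du = -v_s1 * s + v_z1 * c
    n = m * h * u * c + J * w1 * c * c
    dn = m * h * (du * c - u * s) - 2.0 * J * w1 * c * s
    d = m * h * h + J * c * c
    dd = -2.0 * J * c * s
    return (2.0 * n * dn * d - n * n * dd) / (d * d) - 2.0 * m * g * h * s * (2.0 * c - 1.0)


@dataclass
class FpeSolution:
    """Solved contact angle and derived quantities."""

    phi: np.ndarray
    r_F: np.ndarray | None  # world ground point (..., 2) or None
    leg_length: np.ndarray
    w2: np.ndarray
    residual: np.ndarray
    valid: np.ndarray = field(default_factory=lambda: np.array(True))


def _omega2(phi, m, h, v_s1, v_z1, w1, J):
    c = np.cos(phi)
    s = np.sin(phi)
    return (m * h * (v_s1 * c + v_z1 * s) * c + J * w1 * c * c) / (m * h * h + J * c * c)


def solve_fpe(
    inp: FpePlanarInput,
    r_G: np.ndarray | None = None,
    s_hat: np.ndarray | None = None,
    n_bisect: int = 48,
    n_newton: int = 6,
    f_rtol: float = 1e-12,
) -> FpeSolution:
    """Solve f(phi) = 0 by bisection plus a Newton polish.

    The bracket is [0, pi/2) when the initial angular momentum about
    the ground contact, m h v_s1 + J w1, is positive -- which the
    travel-frame construction guarantees.  A net backward momentum is
    handled in the mirrored plane and the angle negated (the balancing
    contact then lies behind the COM ground projection).  f(0) >= 0
    always and f -> 0^- as phi -> pi/2, so a sign change is guaranteed
    whenever the body carries any planar momentum.  Samples with
    non-finite inputs are flagged, not raised.
    """
    m = np.asarray(inp.m, float)
    h = np.asarray(inp.h, float)
    vs = np.asarray(inp.v_s1, float)
    vz = np.asarray(inp.v_z1, float)
    w1 = np.asarray(inp.w1, float)
    J = np.asarray(inp.J, float)
    g = inp.g
    scalar = h.ndim == 0
    m, h, vs, vz, w1, J = np.broadcast_arrays(
        np.atleast_1d(m), np.atleast_1d(h), np.atleast_1d(vs),
        np.atleast_1d(vz), np.atleast_1d(w1), np.atleast_1d(J))
    finite = np.isfinite(m) & np.isfinite(h) & np.isfinite(vs) & \
        np.isfinite(vz) & np.isfinite(w1) & np.isfinite(J) & (h > 0)
    sign = np.where(m * h * vs + J * w1 < 0, -1.0, 1.0)
    vs_m = sign * vs
    w1_m = sign * w1
    hf = np.where(finite, h, 1.0)
    mf = np.where(finite, m, 1.0)
    scale = mf * g * hf

    def f(phi):
        return fpe_residual(phi, mf, hf, vs_m, vz, w1_m, J, g)

    lo = np.zeros_like(hf)
    hi = np.full_like(hf, np.pi / 2 - 1e-9)
    f_lo = f(lo)
    static = f_lo <= f_rtol * scale
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    phi = 0.5 * (lo + hi)
    for _ in range(n_newton):
        fval = f(phi)
        grad = _fpe_residual_grad(phi, mf, hf, vs_m, vz, w1_m, J, g)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = fval / grad
        cand = phi - step
        bad = ~np.isfinite(cand) | (cand < lo) | (cand > hi)
        cand = np.where(bad, 0.5 * (lo + hi), cand)
        pos = f(cand) > 0
        lo = np.where(pos, cand, lo)
        hi = np.where(pos, hi, cand)
        phi = cand
    phi = np.where(static, 0.0, phi)
    res = f(phi)
    valid = finite & (np.abs(res) <= 1e-8 * scale)
    phi_signed = np.where(finite, sign * phi, np.nan)
    leg = hf / np.cos(phi)
    w2 = _omega2(phi, mf, hf, vs_m, vz, w1_m, J)
    r_F = None
    if r_G is not None and s_hat is not None:
        r_G = np.atleast_2d(np.asarray(r_G, float))[..., :2]
        s2 = np.atleast_2d(np.asarray(s_hat, float))[..., :2]
        offset = (hf * np.tan(phi_signed * sign) * sign)[..., None]  # h tan(phi)
        r_F = r_G + offset * s2
        r_F = np.where(valid[..., None], r_F, np.nan)
        if scalar:
            r_F = r_F[0]
    if scalar:
        return FpeSolution(phi=float(phi_signed[0]), r_F=r_F,
                           leg_length=float(leg[0]), w2=float(sign[0] * w2[0]),
                           residual=float(res[0]), valid=bool(valid[0]))
    return FpeSolution(phi=phi_signed, r_F=r_F, leg_length=leg,
                       w2=sign * w2, residual=res, valid=valid)


# ---------------------------------------------------------- stepping outcome


def post_contact_outcome(
    inp: FpePlanarInput,
    contact_offset: float,
    speed_tol: float = 1e-3,
) -> str:
    """Classify the passive outcome of contacting at a given step offset.

    ``contact_offset`` is the distance along s-hat from the COM ground
    projection to the contact point.  Momentum conservation at contact
    gives the post-contact rotation rate w2; the pendulum then rotates
    about the contact with conserved mechanical energy, so the first
    integral decides the motion: if the kinetic energy just after
    contact exceeds the potential-energy gain required to bring the COM
    over the contact point the model passes over and *falls forward*;
    if it is insufficient (or the rotation is initially away from the
    contact) the model reverses and *falls backward*; if the arrival
    rate at upright is within ``speed_tol`` it *balances*.
    """
    m = float(inp.m)
    h = float(inp.h)
    g = inp.g
    vs, w1 = float(inp.v_s1), float(inp.w1)
    # work in the frame where the initial angular momentum about the
    # ground contact is positive (the travel-frame convention); for a
    # net backward-spinning body the geometry and outcome labels mirror
    if m * h * vs + inp.J * w1 < 0:
        out = post_contact_outcome(
            FpePlanarInput(m=m, h=h, v_s1=-vs, v_z1=inp.v_z1, w1=-w1,
                           J=inp.J, g=g),
            -contact_offset, speed_tol)
        return {"falls_forward": "falls_backward",
                "falls_backward": "falls_forward"}.get(out, out)
    phi_c = np.arctan2(contact_offset, h)
    ell = np.hypot(h, contact_offset)
    w2 = float(_omega2(phi_c, m, h, vs, inp.v_z1, w1, inp.J))
    I = inp.J + m * ell**2
    # pendulum angle from upright-over-contact, positive ahead; the COM
    # sits at -phi_c relative to the contact vertical
    theta0 = -phi_c
    fall = {1.0: "falls_forward", -1.0: "falls_backward"}

    def direction(x):
        return 1.0 if x > 0 else -1.0

    toward_upright = (theta0 == 0.0) or (direction(w2) == -direction(theta0))
    if w2 == 0.0:
        return "balances" if theta0 == 0.0 else fall[direction(theta0)]
    if not toward_upright:
        return fall[direction(w2)]
    # rotating toward upright: the first integral decides whether the COM
    # passes over the contact (kinetic energy vs the mg(l - h) climb)
    surplus = 0.5 * I * w2**2 - m * g * (ell - h)
    arrival = np.sqrt(2.0 * abs(surplus) / I)
    if arrival <= speed_tol:
        return "balances"
    return fall[direction(w2) if surplus > 0 else -direction(w2)]


# -------------------------------------------------------------- metric suite


@dataclass
class DynamicMetrics:
    """Per-sample dynamic balance metric series and seat-off values."""

    wz: np.ndarray  # w_avg . z-hat, rad/s
    d_bf: np.ndarray  # signed FPE-to-BOS-edge distance, m
    fpe_cop_t: np.ndarray  # COP -> FPE displacement along t-hat, m
    fpe_cop_s: np.ndarray  # COP -> FPE displacement along s-hat, m
    fpe_point: np.ndarray  # (..., 2) world FPE ground points
    phi: np.ndarray

    def as_dict(self) -> dict:
        return {"wz": self.wz, "d_bf": self.d_bf,
                "fpe_cop_t": self.fpe_cop_t, "fpe_cop_s": self.fpe_cop_s}


def dynamic_metrics(
    state: WholeBodyState,
    bos: BosPolygon,
    cop: np.ndarray,
    mass: float,
) -> DynamicMetrics:
    """Compute the four dynamic balance metric series for a trial."""
    state = _with_mass(state, mass)
    H_G = angular_momentum_about_gp(state)
    frame = travel_frame(H_G, v_C=state.v_C)
    inp = project_state(state, frame, mass=mass)
    sol = solve_fpe(inp, r_G=state.com_gp, s_hat=frame.s)
    wz = state.w_avg[..., 2]
    d_bf = signed_distance(sol.r_F, bos)
    cop = np.asarray(cop, float)
    rel = sol.r_F - cop
    fpe_cop_t = np.einsum("...i,...i->...", rel, frame.t[..., :2])
    fpe_cop_s = np.einsum("...i,...i->...", rel, frame.s[..., :2])
    return DynamicMetrics(wz=wz, d_bf=d_bf, fpe_cop_t=fpe_cop_t,
                          fpe_cop_s=fpe_cop_s, fpe_point=sol.r_F, phi=sol.phi)


def applicability_check(wz: np.ndarray, wz_bound: float) -> np.ndarray:
    """Flag samples whose vertical angular velocity exceeds the bound.

    A flagged sample does not suppress the FPE metrics; it cautions
    their interpretation, since the planar projection assumed by the
    estimator loses information when |w_avg . z-hat| is large.
    """
    return np.abs(np.asarray(wz, float)) <= wz_bound


def _with_mass(state: WholeBodyState, mass: float) -> WholeBodyState:
    state.mass = mass  # annotate for H_G computation
    return state
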