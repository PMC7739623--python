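"""Body segment parameter table for the sagittal three-link model.

The analysis pipeline needs, per segment, a mass, a COM location, an
inertia tensor and the local coordinates of the tracking markers.  For
real recordings these come from a motion-capture model; the synthetic
generator and the tests use the documented table below, expressed as
fractions of total body mass ``M`` and stature ``H``.  The chain is a
planar (sagittal) model: both shanks are merged into one segment, both
thighs into one, and head-arms-trunk (HAT) into one, with the two feet
kept as separate static segments.

All quantities are SI (kg, m, kg m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81  # m/s^2

#: mass fraction, segment length fraction of stature, COM fraction from the
#: proximal joint, radii of gyration (transverse, longitudinal) as fractions
#: of segment length.
SEGMENT_TABLE = {
    # name: (mass_frac, length_frac, com_frac_proximal, k_transverse, k_long)
    "shank": (0.0930, 0.246, 0.433, 0.30, 0.12),
    "thigh": (0.2000, 0.245, 0.433, 0.32, 0.12),
    "hat": (0.6780, 0.350, 0.450, 0.35, 0.18),
    "foot": (0.0145, 0.148, 0.500, 0.25, 0.12),  # per foot
}

#: tracking marker positions in each segment's local frame (origin at the
#: segment COM, z along the long axis pointing proximal->up when standing,
#: x lateral).  Deliberately asymmetric so a rigid least-squares fit is
#: well-conditioned.
SEGMENT_MARKERS = {
    "shank": {
        "SHA1": (0.050, 0.020, 0.100),
        "SHA2": (-0.050, 0.010, 0.120),
        "SHA3": (0.040, -0.030, -0.080),
        "SHA4": (-0.030, 0.045, -0.110),
    },
    "thigh": {
        "THI1": (0.060, 0.025, 0.090),
        "THI2": (-0.055, 0.010, 0.110),
        "THI3": (0.045, -0.035, -0.085),
        "THI4": (-0.035, 0.050, -0.105),
    },
    "hat": {
        "TRX1": (0.070, 0.030, 0.150),
        "TRX2": (-0.065, 0.015, 0.170),
        "TRX3": (0.055, -0.040, -0.120),
        "TRX4": (-0.040, 0.060, -0.160),
    },
}

#: IOR-style foot marker positions in the foot's anatomical frame
#: (origin at the ankle-marker midpoint, x medial for a LEFT foot,
#: y forward, z up), for a foot of width w and length scale drawn from
#: ``foot_marker_local``.
_FOOT_MARKERS_LEFT = {
    # name: (x, y, z) for a left foot, foot pointing +y
    "FAL": (-0.045, 0.000, 0.055),  # lateral malleolus
    "TAM": (0.045, 0.000, 0.060),  # medial malleolus
    "FM1": (0.035, 0.155, 0.025),  # 1st metatarsal head (medial)
    "FM2": (0.005, 0.190, 0.025),  # 2nd metatarsal head (tip of foot length)
    "FM5": (-0.055, 0.130, 0.020),  # 5th metatarsal head (lateral)
    "FCC": (-0.002, -0.060, 0.030),  # heel (calcaneus)
}


#: foot COM position relative to the ankle-marker midpoint (left foot).
_FOOT_COM_OFFSET_LEFT = np.array([0.0, 0.065, 0.028])


def foot_com_offset(side: str) -> np.ndarray:
    """Foot COM relative to the ankle-marker midpoint, world-aligned axes."""
    sign = {"left": 1.0, "right": -1.0}[side]
    return _FOOT_COM_OFFSET_LEFT * np.array([sign, 1.0, 1.0])


def foot_marker_local(side: str) -> dict[str, np.ndarray]:
    """Foot marker coordinates relative to the ankle-marker midpoint.

    The left foot uses the template above; the right foot is its mirror
    image about the sagittal plane (x -> -x).
    """
    sign = {"left": 1.0, "right": -1.0}[side]
    return {
        name: np.array([sign * x, y, z])
        for name, (x, y, z) in _FOOT_MARKERS_LEFT.items()
    }


def _inertia_local(mass: float, length: float, k_t: float, k_l: float) -> np.ndarray:
    """Diagonal inertia tensor about the segment COM in the local frame."""
    it = mass * (k_t * length) ** 2
    il = mass * (k_l * length) ** 2
    return np.diag([it, it, il])


@dataclass
class SegmentParams:
    name: str
    mass: float
    length: float
    com_frac: float  # from the proximal joint, along the long axis
    inertia_local: np.ndarray  # 3x3, about COM, local frame
    markers: dict = field(default_factory=dict)  # name -> local (3,) re COM

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "mass": self.mass,
            "length": self.length,
            "com_frac": self.com_frac,
            "inertia_local": np.asarray(self.inertia_local).tolist(),
            "markers": {k: np.asarray(v).tolist() for k, v in self.markers.items()},
        }

    @classmethod
    def from_json(cls, d: dict) -> "SegmentParams":
        return cls(
            name=d["name"],
            mass=float(d["mass"]),
            length=float(d["length"]),
            com_frac=float(d["com_frac"]),
            inertia_local=np.asarray(d["inertia_local"], dtype=float),
            markers={k: np.asarray(v, dtype=float) for k, v in d["markers"].items()},
        )


@dataclass
class BodyParams:
    """Full body-segment parameter set for one subject."""

    total_mass: float
    stature: float
    segments: dict  # name -> SegmentParams

    @property
    def weight(self) -> float:
        return self.total_mass * GRAVITY

    def to_json(self) -> dict:
        return {
            "total_mass": self.total_mass,
            "stature": self.stature,
            "segments": {k: v.to_json() for k, v in self.segments.items()},
        }

    @classmethod
    def from_json(cls, d: dict) -> "BodyParams":
        return cls(
            total_mass=float(d["total_mass"]),
            stature=float(d["stature"]),
            segments={
                k: SegmentParams.from_json(v) for k, v in d["segments"].items()
            },
        )


def default_body_params(total_mass: float = 75.0, stature: float = 1.72) -> BodyParams:
    """Build the packaged anthropometric parameter set for one subject."""
    segs = {}
    for name in ("shank", "thigh", "hat"):
        mf, lf, cf, kt, kl = SEGMENT_TABLE[name]
        length = lf * stature
        mass = mf * total_mass
        segs[name] = SegmentParams(
            name=name,
            mass=mass,
            length=length,
            com_frac=cf,
            inertia_local=_inertia_local(mass, length, kt, kl),
            markers={k: np.asarray(v, float) for k, v in SEGMENT_MARKERS[name].items()},
        )
    mf, lf, cf, kt, kl = SEGMENT_TABLE["foot"]
    for side in ("left", "right"):
        length = lf * stature
        mass = mf * total_mass
        prefix = side[0].upper()
        segs[f"foot_{side}"] = SegmentParams(
            name=f"foot_{side}",
            mass=mass,
            length=length,
            com_frac=cf,
            inertia_local=_inertia_local(mass, length, kt, kl),
            markers={
                prefix + name: loc - foot_com_offset(side)
                for name, loc in foot_marker_local(side).items()
            },
        )
    return BodyParams(total_mass=total_mass, stature=stature, segments=segs)
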