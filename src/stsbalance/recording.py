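"""Trial containers and the plain-text on-disk dialect.

A :class:`TrialRecording` bundles marker trajectories sampled at the
motion-capture rate with the two force-plate wrenches (seat plate and
foot plate) sampled at the force rate, plus the subject's body-segment
parameters and, for synthetic trials, the generator's ground truth.

On disk a trial is a directory of three TSVs plus a JSON sidecar:

``markers.tsv``
    columns ``time`` then ``<NAME>_x``, ``<NAME>_y``, ``<NAME>_z`` per
    marker, in metres, lab frame (z up, y forward), 0-based samples,
    time in seconds.
``seat_force.tsv`` / ``foot_force.tsv``
    columns ``time``, ``fz`` (N, vertical component, positive up) and
    ``cop_x``, ``cop_y`` (m, lab-frame COP on the plate surface; NaN
    when the plate is unloaded).
``trial.json``
    sampling rates, body parameters, and optional ground-truth events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import BodyParams


@dataclass
class ForcePlate:
    """Vertical force and COP of one plate on a common time base."""

    time: np.ndarray  # (N,) s
    fz: np.ndarray  # (N,) N, positive up
    cop: np.ndarray  # (N, 2) m, lab-frame x/y; NaN when unloaded

    def copy(self) -> "ForcePlate":
        return ForcePlate(self.time.copy(), self.fz.copy(), self.cop.copy())


@dataclass
class StsEvents:
    """Segmented event times of one sit-to-stand repetition."""

    t_init: float = np.nan
    t_seatoff: float = np.nan
    t_stance: float = np.nan
    accepted: bool = False
    rejection_reason: str = "none"

    def to_json(self) -> dict:
        return {
            "t_init": None if np.isnan(self.t_init) else self.t_init,
            "t_seatoff": None if np.isnan(self.t_seatoff) else self.t_seatoff,
            "t_stance": None if np.isnan(self.t_stance) else self.t_stance,
            "accepted": self.accepted,
            "rejection_reason": self.rejection_reason,
        }

    @classmethod
    def from_json(cls, d: dict) -> "StsEvents":
        g = lambda k: np.nan if d.get(k) is None else float(d[k])
        return cls(g("t_init"), g("t_seatoff"), g("t_stance"),
                   bool(d.get("accepted", False)), d.get("rejection_reason", "none"))


@dataclass
class TrialRecording:
    """One synchronized recording (markers + two plates + body params)."""

    time: np.ndarray  # (T,) s, marker clock
    markers: dict  # name -> (T, 3) m
    seat_plate: ForcePlate
    foot_plate: ForcePlate
    f_mocap: float  # Hz
    f_force: float  # Hz
    body_params: BodyParams
    ground_truth: dict | None = None  # generator-side truth (events, series)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ratio = self.f_force / self.f_mocap
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("force rate must be an integer multiple of mocap rate")
        if len(self.markers) != len(set(self.markers)):
            raise ValueError("marker names must be unique")
        for plate in (self.seat_plate, self.foot_plate):
            if not np.all(np.isfinite(plate.fz)):
                raise ValueError("plate forces must be finite")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def marker_array(self, names) -> np.ndarray:
        """Stack selected markers into a (T, k, 3) array."""
        return np.stack([self.markers[n] for n in names], axis=1)

    # ------------------------------------------------------------------ I/O

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cols = {"time": self.time}
        for name, xyz in self.markers.items():
            for i, ax in enumerate("xyz"):
                cols[f"{name}_{ax}"] = xyz[:, i]
        pd.DataFrame(cols).to_csv(path / "markers.tsv", sep="\t", index=False)
        for fname, plate in (("seat_force.tsv", self.seat_plate),
                             ("foot_force.tsv", self.foot_plate)):
            pd.DataFrame({
                "time": plate.time, "fz": plate.fz,
                "cop_x": plate.cop[:, 0], "cop_y": plate.cop[:, 1],
            }).to_csv(path / fname, sep="\t", index=False)
        sidecar = {
            "f_mocap": self.f_mocap,
            "f_force": self.f_force,
            "body_params": self.body_params.to_json(),
            "meta": self.meta,
        }
        if self.ground_truth is not None:
            gt = dict(self.ground_truth)
            if isinstance(gt.get("events"), StsEvents):
                gt["events"] = gt["events"].to_json()
            sidecar["ground_truth"] = {
                k: v for k, v in gt.items()
                if isinstance(v, (int, float, str, bool, dict, list))
            }
        (path / "trial.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, path) -> "TrialRecording":
        path = Path(path)
        sidecar = json.loads((path / "trial.json").read_text())
        mdf = pd.read_csv(path / "markers.tsv", sep="\t")
        time = mdf["time"].to_numpy()
        names = sorted({c[:-2] for c in mdf.columns if c.endswith(("_x", "_y", "_z"))})
        markers = {
            n: np.column_stack([mdf[f"{n}_{ax}"].to_numpy() for ax in "xyz"])
            for n in names
        }
        plates = []
        for fname in ("seat_force.tsv", "foot_force.tsv"):
            fdf = pd.read_csv(path / fname, sep="\t")
            plates.append(ForcePlate(
                time=fdf["time"].to_numpy(),
                fz=fdf["fz"].to_numpy(),
                cop=fdf[["cop_x", "cop_y"]].to_numpy(),
            ))
        gt = sidecar.get("ground_truth")
        if gt is not None and "events" in gt:
            gt = dict(gt)
            gt["events"] = StsEvents.from_json(gt["events"])
        return cls(
            time=time, markers=markers,
            seat_plate=plates[0], foot_plate=plates[1],
            f_mocap=float(sidecar["f_mocap"]), f_force=float(sidecar["f_force"]),
            body_params=BodyParams.from_json(sidecar["body_params"]),
            ground_truth=gt, meta=sidecar.get("meta", {}),
        )
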