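"""Static balance metrics and the still-standing bounds.

A body is statically balanced when it has not fallen and its linear and
angular speeds are *small*, where "small" is operationalized as the
range each metric spans during quiet standing.  Four measurable
conditions are tracked per sample:

* ``d_bg`` -- signed distance from the COM ground projection to the
  nearest BOS edge (positive inside the BOS);
* ``com_cop_dist`` -- distance between COM ground projection and COP
  (nonzero even in still standing because segment models are imperfect);
* ``com_speed`` -- ``||v_C||``;
* ``avg_ang_speed`` -- ``||w_avg||``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bos import BosPolygon, signed_distance
from .kinematics import WholeBodyState

#: metrics whose still-standing range is symmetrized about zero
SIGNED_METRICS = frozenset({"wz"})


@dataclass
class StaticMetrics:
    """Per-sample static balance metric series."""

    d_bg: np.ndarray
    com_cop_dist: np.ndarray
    com_speed: np.ndarray
    avg_ang_speed: np.ndarray

    def as_dict(self) -> dict:
        return {"d_bg": self.d_bg, "com_cop_dist": self.com_cop_dist,
                "com_speed": self.com_speed, "avg_ang_speed": self.avg_ang_speed}


def static_metrics(state: WholeBodyState, cop: np.ndarray, bos: BosPolygon
                   ) -> StaticMetrics:
    """Compute the four static balance series for aligned state/COP data."""
    gp = state.com_gp
    d_bg = signed_distance(gp, bos)
    cop = np.asarray(cop, float)
    com_cop = np.linalg.norm(gp - cop, axis=-1)
    com_speed = np.linalg.norm(state.v_C, axis=-1)
    ang_speed = np.linalg.norm(state.w_avg, axis=-1)
    return StaticMetrics(d_bg=d_bg, com_cop_dist=com_cop,
                         com_speed=com_speed, avg_ang_speed=ang_speed)


def still_standing_bounds(per_subject_metrics, signed=SIGNED_METRICS) -> dict:
    """Per-metric (lower, upper) bounds from quiet-standing recordings.

    ``per_subject_metrics`` is a list (one entry per subject) of dicts
    mapping metric name to a sample series.  For each subject the min
    and max over the window are taken; the bounds are the averages of
    those extrema across subjects.  Signed metrics are symmetrized
    using the larger of the two magnitudes.
    """
    per_subject_metrics = list(per_subject_metrics)
    if not per_subject_metrics:
        raise ValueError("need at least one quiet-standing subject")
    names = per_subject_metrics[0].keys()
    bounds = {}
    for name in names:
        los = [np.nanmin(np.asarray(m[name], float)) for m in per_subject_metrics]
        his = [np.nanmax(np.asarray(m[name], float)) for m in per_subject_metrics]
        lo, hi = float(np.mean(los)), float(np.mean(his))
        if name in signed:
            b = max(abs(lo), abs(hi))
            lo, hi = -b, b
        bounds[name] = (lo, hi)
    return bounds


def is_statically_balanced(sample: dict, bounds: dict) -> bool:
    """Static balance test for one sample of metric values.

    True iff the COM ground projection is inside the BOS (d_bg >= 0)
    and the COM-COP alignment, COM speed and average angular speed all
    lie within their still-standing bounds.
    """
    if not sample.get("d_bg", -1) >= 0:
        return False
    for name in ("com_cop_dist", "com_speed", "avg_ang_speed"):
        lo, hi = bounds[name]
        v = sample[name]
        if not (lo <= v <= hi):
            return False
    return True
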