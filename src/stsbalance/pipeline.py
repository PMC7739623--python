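"""Per-trial analysis orchestration and cohort aggregation.

``analyze_trial`` runs the full chain on one recording: zero-phase
filtering and decimation, rigid segment fits, whole-body state,
two-stage event segmentation, BOS construction from the packaged
template, and the eight balance metric series.  ``extract_seatoff_values``
reduces an analyzed trial to the seat-off metric values plus the two
durations; ``run_cohort`` maps a synthetic cohort through the pipeline
into the tidy table consumed by :func:`stsbalance.stats.compare_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bos import (
    BosPolygon,
    BosTemplate,
    FOOT_MARKERS,
    calibrated_foot_frames,
    default_template,
    foot_dimensions,
    scale_template,
    whole_body_bos,
)
from .fpe import dynamic_metrics
from .kinematics import (
    WholeBodyState,
    preprocess,
    segment_states_from_trial,
)
from .recording import StsEvents, TrialRecording
from .segmentation import segment_trial
from .static_balance import static_metrics

#: the eight balance metrics taken at seat-off, plus the two durations
METRIC_NAMES = ("d_bg", "com_cop_dist", "com_speed", "avg_ang_speed",
                "wz", "d_bf", "fpe_cop_t", "fpe_cop_s")
DURATION_NAMES = ("sts_duration", "rise_duration")


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis pipeline (SI units)."""

    cutoff_hz: float | None = 10.0
    filter_order: int = 4
    max_gap_s: float = 0.1
    cal_window_s: float = 1.0
    min_run_s: float = 0.5
    foot_move_thresh: float = 0.015
    seed: int = 0


@dataclass
class TrialResult:
    """Everything computed for one trial."""

    time: np.ndarray
    state: WholeBodyState
    bos: BosPolygon
    metrics: dict  # name -> series
    events: StsEvents
    all_events: list
    candidates: list
    seatoff: dict | None = None
    meta: dict = field(default_factory=dict)


def balance_metric_series(state: WholeBodyState, bos: BosPolygon,
                          cop: np.ndarray, mass: float) -> dict:
    """All eight balance metric series for aligned state/COP data."""
    sm = static_metrics(state, cop, bos)
    dm = dynamic_metrics(state, bos, cop, mass)
    out = sm.as_dict()
    out.update(dm.as_dict())
    out["fpe_point"] = dm.fpe_point
    return out


def build_trial_bos(trial: TrialRecording, template: BosTemplate,
                    cal_window_s: float = 1.0) -> BosPolygon:
    """Scale the template onto both feet and hull them."""
    frames = calibrated_foot_frames(trial, cal_window_s)
    n = max(2, int(round(cal_window_s * trial.f_mocap)))
    polys = []
    for side in ("left", "right"):
        prefix = side[0].upper()
        mks = {name: trial.markers[prefix + name][:n].mean(axis=0)
               for name in FOOT_MARKERS}
        w, ell = foot_dimensions(mks, side)
        polys.append(scale_template(template, w, ell, frames[side]))
    return whole_body_bos(*polys)


def analyze_trial(
    trial: TrialRecording,
    template: BosTemplate | None = None,
    config: AnalysisConfig | None = None,
) -> TrialResult:
    """Run the full balance analysis on one recording."""
    config = config or AnalysisConfig()
    template = template or default_template()
    pre = preprocess(trial, cutoff_hz=config.cutoff_hz,
                     order=config.filter_order, max_gap_s=config.max_gap_s)
    segments = segment_states_from_trial(pre)
    state = WholeBodyState.from_segments(segments.values())
    mass = pre.body_params.total_mass
    state.mass = mass

    com_height = state.h
    com_speed = np.linalg.norm(state.v_C, axis=-1)
    com_vz = state.v_C[:, 2]
    foot_tracks = {
        prefix + name: pre.markers[prefix + name]
        for prefix in ("L", "R") for name in FOOT_MARKERS
    }
    all_events, candidates = segment_trial(
        com_height, com_speed, com_vz, pre.seat_plate.fz, foot_tracks,
        pre.time, pre.f_mocap, seed=config.seed)
    accepted = [e for e in all_events if e.accepted]
    if accepted:
        events = accepted[0]
    elif all_events:
        events = all_events[0]
    else:
        events = StsEvents(accepted=False, rejection_reason="event_not_found")

    bos = build_trial_bos(pre, template, config.cal_window_s)
    metrics = balance_metric_series(state, bos, pre.foot_plate.cop, mass)
    result = TrialResult(time=pre.time, state=state, bos=bos, metrics=metrics,
                         events=events, all_events=all_events,
                         candidates=candidates, meta=dict(trial.meta))
    if events.accepted:
        result.seatoff = extract_seatoff_values(metrics, events, pre.time, pre.f_mocap)
    return result


def extract_seatoff_values(metrics: dict, events: StsEvents,
                           time: np.ndarray, fs: float) -> dict:
    """Metric values at the seat-off sample plus the two durations."""
    if not events.accepted:
        return {}
    i = int(round((events.t_seatoff - time[0]) * fs))
    i = min(max(i, 0), len(time) - 1)
    out = {}
    for name in METRIC_NAMES:
        v = float(np.asarray(metrics[name])[i])
        out[name] = v
    out["sts_duration"] = events.t_stance - events.t_init
    out["rise_duration"] = events.t_stance - events.t_seatoff
    return out


# ----------------------------------------------------------------- cohorts


def run_cohort(spec, template: BosTemplate | None = None,
               config: AnalysisConfig | None = None,
               condition: str = "side",
               ground_truth: str = "events") -> pd.DataFrame:
    """Analyze a full synthetic cohort into a tidy seat-off table.

    Returns one row per (participant, repetition, metric): columns
    participant, group, condition, repetition, metric, value.  Trials
    whose segmentation rejects every candidate contribute no rows.
    """
    from .synthetic import generate_sts_trial  # synthetic -> pipeline is lazy

    template = template or default_template()
    rows = []
    for subject in range(spec.n_subjects):
        group = spec.group_of(subject)
        for rep in range(spec.reps_per_subject):
            trial = generate_sts_trial(spec, subject, rep,
                                       template=template,
                                       ground_truth=ground_truth)
            result = analyze_trial(trial, template=template, config=config)
            if result.seatoff:
                for metric, value in result.seatoff.items():
                    rows.append({"participant": subject, "group": group,
                                 "condition": condition, "repetition": rep,
                                 "metric": metric, "value": value})
    return pd.DataFrame(rows)


def participant_aggregate(table: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Aggregate repetitions per participant (``mean`` or ``range``).

    ``range`` (max - min over repetitions) is the within-subject
    variability measure; its metrics are suffixed ``_range``.
    """
    keys = ["participant", "group", "condition", "metric"]
    if how == "mean":
        agg = table.groupby(keys, as_index=False)["value"].mean()
    elif how == "range":
        agg = table.groupby(keys, as_index=False)["value"].agg(np.ptp)
        agg["metric"] = agg["metric"] + "_range"
    else:
        raise ValueError("how must be 'mean' or 'range'")
    return agg
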