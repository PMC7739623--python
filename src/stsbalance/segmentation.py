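"""Two-stage automatic segmentation of sit-to-stand repetitions.

Stage one clusters two signals -- the whole-body COM height and the
seat-plate vertical force -- into three groups each with k-means++, and
labels the clusters by their means: for height, lowest = seated,
highest = standing, the rest = crouch/transition; for force, largest =
seated, lowest = standing, the rest = transition.  Candidate sequences
are standing-height runs (>= 0.5 s) connected backwards in time to a
seated-force run (>= 0.5 s) with exactly one transition-force ->
standing-force switch in between, and with the feet stationary (at
least 3 of the 6 markers of each foot must move < 15 mm vertically).

Stage two refines the three event times with adaptive thresholds:
initiation where the COM speed first rises 1 cm/s above its minimum in
the seated-force set, seat-off where the seat force first comes within
1 N of its unloaded (standing) reading, and stance where the COM is
within 1 cm of the median standing height while moving slower than
1 cm/s vertically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .recording import StsEvents

SEATED, TRANSITION, STANDING = 0, 1, 2
LABEL_NAMES = {SEATED: "seated", TRANSITION: "transition", STANDING: "standing"}

REJECTION_REASONS = ("none", "foot_moved", "short_standing", "short_sitting",
                     "multiple_transitions", "sit_back", "event_not_found")


@dataclass
class ClusterLabels:
    """Per-sample phase labels for one clustered signal."""

    labels: np.ndarray  # (T,) int codes SEATED/TRANSITION/STANDING
    means: dict  # code -> cluster mean


@dataclass
class Candidate:
    """One candidate sit-to-stand interval (sample indices, inclusive)."""

    start: int
    end: int
    accepted: bool
    reason: str = "none"


def cluster_signal(signal: np.ndarray, kind: str, seed: int = 0,
                   n_restarts: int = 10) -> ClusterLabels:
    """Three-cluster k-means++ labeling of a height or force signal.

    ``kind`` selects the label-by-mean convention: ``"height"`` maps the
    lowest-mean cluster to seated and the highest to standing;
    ``"force"`` maps the largest-mean cluster to seated and the lowest
    to standing (the seat plate is loaded while sitting).
    """
    x = np.asarray(signal, float).reshape(-1, 1)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct values to form 3 clusters")
    km = KMeans(n_clusters=3, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(x)
    means = km.cluster_centers_.ravel()
    order = np.argsort(means)  # ascending
    if kind == "height":
        code_of = {order[0]: SEATED, order[1]: TRANSITION, order[2]: STANDING}
    elif kind == "force":
        code_of = {order[2]: SEATED, order[1]: TRANSITION, order[0]: STANDING}
    else:
        raise ValueError("kind must be 'height' or 'force'")
    labels = np.array([code_of[k] for k in km.labels_])
    return ClusterLabels(labels=labels,
                         means={code_of[i]: float(means[i]) for i in range(3)})


def _runs(labels: np.ndarray):
    """Contiguous runs as (value, start, end_inclusive) triples."""
    labels = np.asarray(labels)
    changes = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, changes]
    ends = np.r_[changes - 1, len(labels) - 1]
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _feet_stationary(foot_tracks: dict, start: int, end: int,
                     thresh: float = 0.015) -> bool:
    """At least 3 of each foot's 6 markers move < 15 mm vertically."""
    for prefix in ("L", "R"):
        names = [n for n in foot_tracks if n.startswith(prefix)]
        still = 0
        for n in names:
            z = foot_tracks[n][start:end + 1, 2]
            if np.ptp(z) < thresh:
                still += 1
        if still < 3:
            return False
    return True


def candidate_sequences(
    height_labels: ClusterLabels,
    force_labels: ClusterLabels,
    foot_tracks: dict,
    fs: float,
    min_run_s: float = 0.5,
    foot_thresh: float = 0.015,
) -> list:
    """Identify candidate sit-to-stand intervals with rejection reasons."""
    hl = height_labels.labels
    fl = force_labels.labels
    min_len = int(round(min_run_s * fs))
    candidates = []
    force_runs = _runs(fl)
    for value, s, e in _runs(hl):
        if value != STANDING:
            continue
        if e - s + 1 < min_len:
            candidates.append(Candidate(s, e, False, "short_standing"))
            continue
        seated_before = np.flatnonzero(fl[:s] == SEATED)
        if seated_before.size == 0:
            candidates.append(Candidate(s, e, False, "short_sitting"))
            continue
        j = int(seated_before[-1])
        run = next(r for r in force_runs if r[1] <= j <= r[2])
        if run[2] - run[1] + 1 < min_len:
            candidates.append(Candidate(run[1], e, False, "short_sitting"))
            continue
        seg = fl[j:s + 1]
        n_trans = int(np.sum((seg[:-1] == TRANSITION) & (seg[1:] == STANDING)))
        if n_trans != 1:
            candidates.append(Candidate(run[1], e, False, "multiple_transitions"))
            continue
        if not _feet_stationary(foot_tracks, run[1], e, foot_thresh):
            candidates.append(Candidate(run[1], e, False, "foot_moved"))
            continue
        candidates.append(Candidate(run[1], e, True, "none"))
    # sit-back failures: the stool is unloaded and re-loaded with no
    # successfully completed stand in between
    seated_runs = [r for r in force_runs if r[0] == SEATED and r[2] - r[1] + 1 >= min_len]
    for (_, s1, e1), (_, s2, e2) in zip(seated_runs, seated_runs[1:]):
        stood = any(c.accepted and c.start <= s2 and c.end >= e1
                    for c in candidates)
        if not stood:
            candidates.append(Candidate(e1 + 1, s2 - 1, False, "sit_back"))
    return candidates


def refine_events(
    candidate: Candidate,
    com_speed: np.ndarray,
    seat_force: np.ndarray,
    com_height: np.ndarray,
    com_vz: np.ndarray,
    height_labels: ClusterLabels,
    force_labels: ClusterLabels,
    time: np.ndarray,
    init_speed_delta: float = 0.01,
    seatoff_force_tol: float = 1.0,
    stance_height_tol: float = 0.01,
    stance_speed_tol: float = 0.01,
) -> StsEvents:
    """Refine initiation, seat-off and stance times within an interval."""
    if not candidate.accepted:
        return StsEvents(accepted=False, rejection_reason=candidate.reason)
    s, e = candidate.start, candidate.end
    hl, fl = height_labels.labels, force_labels.labels
    seated_idx = np.flatnonzero(fl[s:e + 1] == SEATED) + s
    standing_idx = np.flatnonzero(hl == STANDING)
    if seated_idx.size == 0 or standing_idx.size == 0:
        return StsEvents(accepted=False, rejection_reason="event_not_found")
    vmin = np.nanmin(com_speed[seated_idx])
    i_min = int(seated_idx[np.nanargmin(com_speed[seated_idx])])
    above = np.flatnonzero(com_speed[i_min:e + 1] >= vmin + init_speed_delta)
    if above.size == 0:
        return StsEvents(accepted=False, rejection_reason="event_not_found")
    i_init = i_min + int(above[0])
    f_ref = float(np.nanmedian(seat_force[standing_idx]))
    near = np.flatnonzero(np.abs(seat_force[i_init:e + 1] - f_ref) <= seatoff_force_tol)
    if near.size == 0:
        return StsEvents(accepted=False, rejection_reason="event_not_found")
    i_so = i_init + int(near[0])
    h_med = float(np.nanmedian(com_height[standing_idx]))
    ok = np.flatnonzero(
        (np.abs(com_height[i_so:e + 1] - h_med) <= stance_height_tol)
        & (np.abs(com_vz[i_so:e + 1]) < stance_speed_tol))
    if ok.size == 0:
        return StsEvents(accepted=False, rejection_reason="event_not_found")
    i_st = i_so + int(ok[0])
    if not (i_init < i_so < i_st):
        return StsEvents(accepted=False, rejection_reason="event_not_found")
    return StsEvents(t_init=float(time[i_init]), t_seatoff=float(time[i_so]),
                     t_stance=float(time[i_st]), accepted=True)


def segment_trial(
    com_height: np.ndarray,
    com_speed: np.ndarray,
    com_vz: np.ndarray,
    seat_force: np.ndarray,
    foot_tracks: dict,
    time: np.ndarray,
    fs: float,
    seed: int = 0,
) -> tuple[list, list]:
    """Run both segmentation stages on one trial's aligned 150 Hz series.

    Returns ``(events, candidates)`` where events holds one
    :class:`StsEvents` per candidate (accepted or not), in time order.
    """
    hlab = cluster_signal(com_height, "height", seed=seed)
    flab = cluster_signal(seat_force, "force", seed=seed)
    cands = candidate_sequences(hlab, flab, foot_tracks, fs)
    events = [
        refine_events(c, com_speed, seat_force, com_height, com_vz, hlab, flab, time)
        for c in cands
    ]
    return events, cands
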