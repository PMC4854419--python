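"""From simulated trajectories to percepts, dominance durations, and
switch-mechanism classification.

The most active pool at a decision time (end of each change-detector
pulse) is the percept.  Quartet labels carry orientation (H/V) and
rotation direction (+/-); grouping over the fast direction oscillation
gives orientation percepts whose uninterrupted runs are the dominance
durations T_D, counted in movie frames.  Direction-persistent orbits
(V+, H+, V+, ...) are the rotation percept and are excluded from
orientation T_D summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import CircuitParams, CircuitState, Trajectory, integrate

__all__ = [
    "PerceptTrace",
    "DominanceRecord",
    "dominant_labels",
    "dominance_records",
    "records_to_frame",
    "sweep_dynamic_L4",
    "habituation_curve",
    "classify_switch",
    "ALLOWED_QUARTET_TRANSITIONS",
]

# Table of quartet percept transitions allowed by the stimulus parity:
# the stimulated pair alternates, so the next percept must come from
# the other pair.
ALLOWED_QUARTET_TRANSITIONS = {
    "V+": frozenset({"V-", "H+"}),
    "H-": frozenset({"V-", "H+"}),
    "V-": frozenset({"V+", "H-"}),
    "H+": frozenset({"V+", "H-"}),
}

_ORIENTATION = {"V+": "V", "V-": "V", "H+": "H", "H-": "H", "H": "H", "V": "V"}
_DIRECTION = {"V+": "+", "V-": "-", "H+": "+", "H-": "-"}


@dataclass
class PerceptTrace:
    """Per-transition dominant labels and the times they were scored."""

    labels: list  # one raw pool label (or "none") per frame transition
    decision_times: np.ndarray

    def __post_init__(self):
        if len(self.labels) != len(self.decision_times):
            raise ValueError("one label per decision time required")

    def orientation_tokens(self, rotation_min_run: int = 3) -> list:
        """Orientation sequence with direction-persistent stretches of at
        least ``rotation_min_run`` transitions relabelled "rotation"."""
        toks = [_ORIENTATION.get(lab, "none") for lab in self.labels]
        dirs = [_DIRECTION.get(lab) for lab in self.labels]
        if any(d is not None for d in dirs):
            i = 0
            n = len(dirs)
            while i < n:
                j = i
                while (
                    j + 1 < n
                    and dirs[j + 1] is not None
                    and dirs[j + 1] == dirs[j]
                ):
                    j += 1
                if dirs[i] is not None and j - i + 1 >= rotation_min_run:
                    for k in range(i, j + 1):
                        toks[k] = "rotation"
                i = j + 1
        return toks


@dataclass(frozen=True)
class DominanceRecord:
    """One uninterrupted dominance period: 1-based epoch, percept label,
    duration T_D in frames, and whether the run end-truncated it."""

    epoch: int
    label: str
    T_D: int
    censored: bool

    def __post_init__(self):
        if self.T_D < 1:
            raise ValueError("T_D is a frame count >= 1")
        if self.epoch < 1:
            raise ValueError("epochs are 1-based")


def dominant_labels(
    traj: Trajectory, decision_times, *, zero_atol: float = 1e-12
) -> PerceptTrace:
    """Score the dominant pool at each decision time.

    Ties retain the previously dominant label (perceptual hysteresis);
    an initial tie goes to the lowest pool index.  If every pool is at
    zero activity the transition is labelled "none".
    """
    decision_times = np.asarray(decision_times, dtype=float)
    if len(decision_times) == 0:
        raise ValueError("no decision times supplied")
    if decision_times.min() < traj.times[0] - 1e-9 or decision_times.max() > traj.times[-1] + 1e-9:
        raise ValueError("decision times outside the trajectory span")
    labels = []
    prev = None
    pool_labels = list(traj.pool_labels)
    for t in decision_times:
        u = traj.u[traj.index_at_time(t)]
        if np.all(u <= zero_atol):
            labels.append("none")
            continue
        top = np.flatnonzero(u == u.max())
        if len(top) > 1 and prev in [pool_labels[i] for i in top]:
            lab = prev
        else:
            lab = pool_labels[top[0]]
        labels.append(lab)
        prev = lab
    return PerceptTrace(labels=labels, decision_times=decision_times)


def dominance_records(trace: PerceptTrace) -> list:
    """Run-length encode the orientation percept sequence.

    "none" transitions are dropped before encoding; the final record of
    every run is right-censored (the percept may have outlived the
    simulation or block).
    """
    toks = [t for t in trace.orientation_tokens() if t != "none"]
    if not toks:
        raise ValueError("empty percept trace: nothing to encode")
    records = []
    run_label = toks[0]
    run_len = 0
    for tok in toks:
        if tok == run_label:
            run_len += 1
        else:
            records.append(
                DominanceRecord(len(records) + 1, run_label, run_len, False)
            )
            run_label = tok
            run_len = 1
    records.append(DominanceRecord(len(records) + 1, run_label, run_len, True))
    return records


def records_to_frame(records, **constants) -> pd.DataFrame:
    """DominanceRecord list -> tidy DataFrame; extra keyword constants
    (run_id, T_frame_ms, ...) become columns."""
    df = pd.DataFrame(
        {
            "epoch": [r.epoch for r in records],
            "label": [r.label for r in records],
            "T_D_frames": [r.T_D for r in records],
            "censored": [r.censored for r in records],
        }
    )
    for k, v in constants.items():
        df[k] = v
    return df


def _orientation_records(records):
    return [r for r in records if r.label in ("H", "V")]


def sweep_dynamic_L4(
    params: CircuitParams,
    make_schedule,
    T_frame_grid,
    horizon_frames: int,
    *,
    state0: CircuitState | None = None,
    dt: float | None = None,
    record_every: int = 5,
) -> pd.DataFrame:
    """Mean uncensored dominance duration per frame interval.

    ``make_schedule(T_frame_ms, n_frames)`` builds the drive schedule
    for one run; every run starts from ``state0`` (rested by default).
    A run with no percept alternation within the horizon is flagged
    ``no_alternation`` and contributes no uncensored duration.
    """
    if horizon_frames < 1:
        raise ValueError("horizon must cover at least one frame")
    rows = []
    for T_frame in T_frame_grid:
        sched = make_schedule(float(T_frame), int(horizon_frames))
        start = (state0 or CircuitState.rested(params.n_pools)).copy()
        traj = integrate(
            params, start, sched, sched.span, dt=dt, record_every=record_every
        )
        trace = dominant_labels(traj, sched.decision_times)
        records = _orientation_records(dominance_records(trace))
        uncensored = [r.T_D for r in records if not r.censored]
        rows.append(
            {
                "T_frame_ms": float(T_frame),
                "mean_T_D": float(np.mean(uncensored)) if uncensored else np.nan,
                "n_uncensored": len(uncensored),
                "no_alternation": len(uncensored) == 0,
            }
        )
    return pd.DataFrame(rows)


def habituation_curve(records) -> pd.DataFrame:
    """T_D across percept epochs (uncensored orientation records only)."""
    rec = [r for r in _orientation_records(records) if not r.censored]
    if len(rec) < 2:
        raise ValueError("need at least two uncensored records for a curve")
    return pd.DataFrame(
        {"epoch": [r.epoch for r in rec], "T_D_frames": [r.T_D for r in rec]}
    )


def classify_switch(
    traj: Trajectory,
    trace: PerceptTrace,
    switch_index: int,
    params: CircuitParams,
    S_on: float,
    S_off: float,
) -> str:
    """Classify the dominance switch at transition ``switch_index`` as
    "escape" or "release".

    An asymmetric state with pool d dominant requires both (i) enough
    inhibition to keep the challenger silent,
    ``s_cd * b * f(S - gamma*a_d) + gamma*a_c > S``, and (ii) the
    dominant pool's fatigue below the off-state background,
    ``S_off > gamma*a_d``.  Operationally, the trajectory between the
    previous decision time and the switch is scanned: if the fatigue
    clause fails at any off-state sample (the dominant pool can no
    longer stay active on background input alone) the switch is a
    release; otherwise the incumbent was still holding its off-state
    activity and the challenger overcame its inhibition during a pulse,
    which is an escape.  In fast pulsed protocols escape can occur
    through the on-state transient before the static clause
    ``s_cd * b * f(S_on) + gamma*a_c < S_on`` is reached, so escape is
    identified by the takeover itself rather than by that inequality.
    """
    toks = trace.orientation_tokens()
    if switch_index < 1 or switch_index >= len(toks):
        raise ValueError("switch index out of range")
    if toks[switch_index] == toks[switch_index - 1]:
        raise ValueError("no labelled switch at this transition")
    labels = list(traj.pool_labels)

    def pool_of(tok, idx):
        raw = trace.labels[idx]
        return labels.index(raw)

    d = pool_of(toks[switch_index - 1], switch_index - 1)  # outgoing dominant
    c = pool_of(toks[switch_index], switch_index)  # incoming challenger
    t_lo = trace.decision_times[switch_index - 1]
    t_hi = trace.decision_times[switch_index]
    i_lo, i_hi = traj.index_at_time(t_lo), traj.index_at_time(t_hi)
    gamma = params.local_fatigue_strength
    on_level = S_off + 0.5 * (S_on - S_off)
    took_over = traj.u[i_hi, c] > traj.u[i_hi, d]
    if not took_over:
        raise ValueError(
            "challenger is not dominant at the switch decision time: "
            "not a true switch"
        )
    for i in range(i_lo, i_hi + 1):
        off_state = traj.drive[i, d] < on_level
        if off_state and gamma * traj.a[i, d] >= S_off:
            return "release"
    return "escape"
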