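import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rivalry.circuit import Trajectory
from rivalry.readout import (
    ALLOWED_QUARTET_TRANSITIONS,
    PerceptTrace,
    classify_switch,
    dominance_records,
    dominant_labels,
    habituation_curve,
    sweep_dynamic_L4,
)
from rivalry.recipes import run_intermittent


def _toy_traj(u_rows, labels=("H", "V")):
    u = np.asarray(u_rows, dtype=float)
    n = u.shape[1]
    t = 100.0 * np.arange(len(u))
    return Trajectory(
        times=t,
        u=u,
        a=np.zeros_like(u),
        s=np.ones((len(u), n, n)),
        drive=np.zeros_like(u),
        pool_labels=tuple(labels),
    )


def test_dominant_label_is_argmax():
    traj = _toy_traj([[0.5, 0.1], [0.1, 0.6]])
    trace = dominant_labels(traj, [0.0, 100.0])
    assert trace.labels == ["H", "V"]


def test_tie_retains_previous_label():
    traj = _toy_traj([[0.5, 0.1], [0.3, 0.3], [0.3, 0.3]])
    trace = dominant_labels(traj, [0.0, 100.0, 200.0])
    assert trace.labels == ["H", "H", "H"]


def test_initial_tie_goes_to_lowest_pool_index():
    traj = _toy_traj([[0.2, 0.2]])
    assert dominant_labels(traj, [0.0]).labels == ["H"]


def test_all_zero_activity_labels_none():
    traj = _toy_traj([[0.0, 0.0], [0.4, 0.1]])
    trace = dominant_labels(traj, [0.0, 100.0])
    assert trace.labels == ["none", "H"]


def test_decision_times_must_lie_in_span():
    traj = _toy_traj([[0.5, 0.1]])
    with pytest.raises(ValueError, match="span"):
        dominant_labels(traj, [500.0])


@pytest.mark.parametrize(
    "labels, expected",
    [
        (["V", "V", "V", "H", "H"], [(1, "V", 3, False), (2, "H", 2, True)]),
        (["V"], [(1, "V", 1, True)]),
        (
            ["V", "H", "V", "H"],
            [(1, "V", 1, False), (2, "H", 1, False), (3, "V", 1, False),
             (4, "H", 1, True)],
        ),
    ],
)
def test_dominance_records_run_length_encoding(labels, expected):
    trace = PerceptTrace(labels=labels, decision_times=np.arange(len(labels), dtype=float))
    recs = dominance_records(trace)
    assert [(r.epoch, r.label, r.T_D, r.censored) for r in recs] == expected


@settings(derandomize=True, max_examples=150)
@given(st.lists(st.sampled_from(["H", "V"]), min_size=1, max_size=60))
def test_run_length_encoding_inverts(labels):
    trace = PerceptTrace(labels=labels, decision_times=np.arange(len(labels), dtype=float))
    recs = dominance_records(trace)
    rebuilt = [r.label for r in recs for _ in range(r.T_D)]
    assert rebuilt == labels
    assert [r.epoch for r in recs] == list(range(1, len(recs) + 1))
    assert all(a.label != b.label for a, b in zip(recs, recs[1:]))
    assert recs[-1].censored and not any(r.censored for r in recs[:-1])


def test_rotation_orbits_are_detected_and_excluded():
    labels = ["V+", "V-", "V+", "H-", "V-", "H-", "V-"]
    trace = PerceptTrace(labels=labels, decision_times=np.arange(7.0))
    toks = trace.orientation_tokens()
    assert toks[3:7] == ["rotation"] * 4
    assert toks[:3] == ["V", "V", "V"]


def test_quartet_memory_run_oscillates_direction(quartet_run):
    """Orientation persists across transitions while direction flips
    every frame (V+, V-, V+, ...)."""
    _, trace, records = quartet_run
    first = trace.labels[:6]
    assert first[0][0] == first[1][0] == first[2][0]  # same orientation
    dirs = [lab[1] for lab in first]
    assert dirs[:4] == [dirs[0], "-" if dirs[0] == "+" else "+", dirs[0],
                        "-" if dirs[0] == "+" else "+"]
    # and the run eventually switches orientation
    assert any(r.label == "V" for r in records) and any(
        r.label == "H" for r in records
    )


def test_quartet_trace_satisfies_allowed_transition_table(quartet_run):
    _, trace, _ = quartet_run
    labs = [l for l in trace.labels if l != "none"]
    for a, b in zip(labs, labs[1:]):
        assert b in ALLOWED_QUARTET_TRANSITIONS[a]


def test_habituation_local_fatigue_decreasing(local_run):
    _, _, records = local_run
    curve = habituation_curve(records)["T_D_frames"].to_numpy()
    assert curve[0] > curve[1]
    assert np.all(np.diff(curve[:4]) <= 0)
    # steady state: late epochs essentially constant
    assert np.std(curve[-5:]) <= 1.0


def test_habituation_nonlocal_fatigue_first_epoch_shorter(nonlocal_run):
    _, _, records = nonlocal_run
    curve = habituation_curve(records)["T_D_frames"].to_numpy()
    assert curve[0] < curve[1]


def test_habituation_curve_needs_two_events():
    trace = PerceptTrace(labels=["V"], decision_times=np.array([0.0]))
    with pytest.raises(ValueError):
        habituation_curve(dominance_records(trace))


def test_switch_classification_local_is_release(local_profile, local_run):
    traj, trace, _ = local_run
    toks = trace.orientation_tokens()
    sw = next(i for i in range(1, len(toks)) if toks[i] != toks[i - 1])
    mech = classify_switch(
        traj, trace, sw, local_profile.params, local_profile.S_on,
        local_profile.S_off
    )
    assert mech == "release"


def test_switch_classification_nonlocal_is_escape(nonlocal_profile, nonlocal_run):
    traj, trace, _ = nonlocal_run
    toks = trace.orientation_tokens()
    sw = next(i for i in range(1, len(toks)) if toks[i] != toks[i - 1])
    mech = classify_switch(
        traj, trace, sw, nonlocal_profile.params, nonlocal_profile.S_on,
        nonlocal_profile.S_off
    )
    assert mech == "escape"


def test_classify_rejects_non_switch(local_profile, local_run):
    traj, trace, _ = local_run
    toks = trace.orientation_tokens()
    idx = next(i for i in range(1, len(toks)) if toks[i] == toks[i - 1])
    with pytest.raises(ValueError, match="switch"):
        classify_switch(
            traj, trace, idx, local_profile.params, local_profile.S_on,
            local_profile.S_off
        )


def test_sweep_requires_positive_horizon(local_profile):
    with pytest.raises(ValueError, match="horizon"):
        sweep_dynamic_L4(local_profile.params, lambda T, n: None, [300.0], 0)
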