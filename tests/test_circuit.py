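import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rivalry.circuit import (
    CircuitParams,
    CircuitState,
    GainFunction,
    build_quartet,
    build_two_pool,
    derivatives,
    integrate,
)
from rivalry.stimulus import ConstantDrive


# ---------------------------------------------------------------------------
# gain function
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected", [(-1.0, 0.0), (0.0, 0.0), (4.0, 2.0), (0.25, 0.5)]
)
def test_hard_gain_is_sqrt_of_positive_part(x, expected):
    g = GainFunction()
    assert g(x) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(
    x=st.floats(-5, 5),
    eps=st.sampled_from([1e-3, 1e-2, 0.1, 0.5]),
)
def test_smoothed_gain_matches_contract(x, eps):
    g = GainFunction("smoothed", smoothing_scale=eps)
    y = g(x)
    assert y >= 0
    if x <= 0:
        assert y == 0.0
    # non-decreasing
    assert g(x + 0.01) >= y - 1e-12


@settings(derandomize=True, max_examples=200)
@given(
    a=st.floats(1e-6, 5),
    b=st.floats(1e-6, 5),
    variant=st.sampled_from(["hard", "smoothed"]),
)
def test_gain_concave_for_positive_argument(a, b, variant):
    g = GainFunction(variant, smoothing_scale=0.1 if variant == "smoothed" else 0.0)
    mid = 0.5 * (a + b)
    assert g(mid) >= 0.5 * (g(a) + g(b)) - 1e-12


def test_smoothed_gain_converges_pointwise_to_hard():
    hard = GainFunction()
    for x in (-1.0, 0.05, 0.5, 2.0):
        vals = [
            GainFunction("smoothed", smoothing_scale=eps)(x)
            for eps in (1e-1, 1e-3, 1e-6)
        ]
        errs = [abs(v - hard(x)) for v in vals]
        assert errs[-1] <= 1e-4
        assert errs == sorted(errs, reverse=True) or errs[-1] == 0.0


def test_smoothed_gain_requires_positive_scale():
    with pytest.raises(ValueError):
        GainFunction("smoothed", smoothing_scale=0.0)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------


def _plain_params(n=2, **kw):
    return CircuitParams(
        n_pools=n,
        weights=np.zeros((n, n)),
        local_fatigue_strength=kw.get("gamma", 0.0),
        nonlocal_fatigue_strength=kw.get("phi", 0.0),
        tau_u_ms=kw.get("tau_u", 10.0),
        tau_a_ms=2000.0,
        tau_s_ms=2000.0,
    )


def test_rest_is_a_fixed_point():
    p = build_two_pool(1.5, local_fatigue_strength=0.3)
    du, da, ds = derivatives(CircuitState.rested(2), np.zeros(2), p)
    assert np.all(du == 0) and np.all(da == 0) and np.all(ds == 0)


def test_drive_onto_rested_pool_gives_sqrt_drive_rate():
    p = _plain_params()
    du, _, _ = derivatives(CircuitState.rested(2), np.array([0.81, 0.0]), p)
    assert du[0] == pytest.approx(0.9 / p.tau_u_ms)
    assert du[1] == 0.0


def test_depressed_synapses_recover_when_presynaptic_pools_silent():
    p = build_two_pool(1.5, nonlocal_fatigue_strength=3.0)
    st_ = CircuitState(np.zeros(2), np.zeros(2), 0.4 * np.ones((2, 2)))
    _, _, ds = derivatives(st_, np.zeros(2), p)
    assert np.all(ds > 0)


def test_derivatives_rejects_dimension_mismatch():
    p = build_two_pool(1.0)
    with pytest.raises(ValueError):
        derivatives(CircuitState.rested(2), np.zeros(3), p)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def test_integrator_refuses_large_steps():
    p = build_two_pool(1.0)
    with pytest.raises(ValueError, match="dt"):
        integrate(p, CircuitState.rested(2), ConstantDrive([0, 0]), (0, 100), dt=5.0)


def test_subthreshold_drive_keeps_rest():
    p = build_two_pool(1.0)
    traj = integrate(p, CircuitState.rested(2), ConstantDrive([-0.5, -0.5]), (0, 500))
    assert np.all(traj.u == 0) and np.all(traj.a == 0)


def test_single_pool_relaxation_matches_closed_form():
    # uncoupled pool, constant drive S, no fatigue:
    # u(t) = sqrt(S) * (1 - exp(-t / tau_u))
    p = _plain_params()
    S = 0.81
    traj = integrate(
        p, CircuitState.rested(2), ConstantDrive([S, 0.0]), (0, 80), record_every=1
    )
    expected = np.sqrt(S) * (1 - np.exp(-traj.times / p.tau_u_ms))
    assert np.max(np.abs(traj.u[:, 0] - expected)) < 1e-6


def test_half_step_convergence_on_smooth_trajectory():
    p = build_two_pool(1.5, local_fatigue_strength=0.3)
    state = CircuitState(np.array([0.4, 0.1]), np.zeros(2), np.ones((2, 2)))
    drive = ConstantDrive([0.5, 0.5])
    end_full = integrate(p, state, drive, (0, 2000), dt=0.5).u[-1]
    end_half = integrate(p, state, drive, (0, 2000), dt=0.25).u[-1]
    assert np.max(np.abs(end_full - end_half)) < 1e-7


def test_state_invariants_hold_along_trajectories(local_profile):
    prof = local_profile
    traj = integrate(
        prof.params,
        CircuitState(np.array([0.8, 0.2]), np.array([0.1, 0.0]), np.ones((2, 2))),
        ConstantDrive([prof.S_on, prof.S_on]),
        (0, 20000),
        record_every=5,
    )
    assert np.all(traj.u >= 0)
    assert np.all(traj.a >= 0)
    assert np.all(traj.s > 0) and np.all(traj.s <= 1)
    assert np.all(np.diff(traj.times) > 0)


def test_persistent_activity_bistability(persistent_profile):
    """Reciprocal excitation in the critical window: a pulsed pool stays
    elevated at zero drive, and a hard reset to zero stays at zero."""
    p = persistent_profile.params
    kick = integrate(
        p, CircuitState.rested(2), ConstantDrive([0.5, 0.0]), (0, 500)
    ).final_state
    held = integrate(p, kick, ConstantDrive([0.0, 0.0]), (0, 20000))
    assert held.u[-1, 0] > 0.5
    reset = held.final_state
    reset.u[:] = 0.0
    back = integrate(p, reset, ConstantDrive([0.0, 0.0]), (0, 20000))
    assert np.all(back.u[-1] == 0.0)


def test_quartet_symmetry_equivariance(quartet_profile):
    """Permuting pools by the stimulus symmetry (swap H/V) and permuting
    the drive identically permutes the trajectory."""
    p = quartet_profile.params
    perm = [2, 3, 0, 1]  # V+,V-,H+,H- -> H+,H-,V+,V-
    drive = np.array([0.5, 0.02, 0.1, 0.02])
    state = CircuitState(
        np.array([0.3, 0.0, 0.05, 0.0]), np.zeros(4), np.ones((4, 4))
    )
    t1 = integrate(p, state, ConstantDrive(drive), (0, 3000), record_every=10)
    state_p = CircuitState(
        state.u[perm], state.a[perm], state.s[np.ix_(perm, perm)]
    )
    t2 = integrate(
        p, state_p, ConstantDrive(drive[perm]), (0, 3000), record_every=10
    )
    assert np.allclose(t1.u[:, perm], t2.u, atol=1e-12)
    assert np.allclose(t1.a[:, perm], t2.a, atol=1e-12)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def test_quartet_weight_matrix_respects_symmetry_group():
    p = build_quartet(1.5, like_orientation=0.2, like_direction=0.05)
    w = p.weights
    for perm in ([2, 3, 0, 1], [1, 0, 3, 2]):  # swap H/V; swap +/-
        assert np.array_equal(w, w[np.ix_(perm, perm)])
    # competing pairs inhibit, like pairs excite
    assert w[0, 3] < 0 and w[1, 2] < 0
    assert w[0, 1] > 0 and w[0, 2] > 0


def test_quartet_rejects_bad_sign_pattern():
    with pytest.raises(ValueError):
        build_quartet(-1.0, like_orientation=0.2, like_direction=0.05)
    with pytest.raises(ValueError):
        build_quartet(1.0, like_orientation=-0.2, like_direction=0.05)


def test_degenerate_quartet_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        build_quartet(1.0, like_orientation=0.0, like_direction=0.0)


def test_two_pool_spec():
    p = build_two_pool(1.0)
    assert np.array_equal(p.weights, [[0.0, -1.0], [-1.0, 0.0]])
    assert p.pool_labels == ("H", "V")
    with pytest.raises(ValueError):
        build_two_pool(0.0)
    with pytest.raises(ValueError):
        build_two_pool(-2.0)


def test_fatigue_time_scale_separation_enforced():
    with pytest.raises(ValueError, match="slower"):
        build_two_pool(1.0, tau_a_ms=50.0, tau_u_ms=10.0)
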