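"""Fixed points, the mutual-inhibition memory condition, and bifurcation
scans for the reduced two-pool circuit.

Under static symmetric drive S the two-pool circuit passes, as S grows,
from a symmetric phase through a pitchfork at S = 0 into a
winner-take-all (asymmetric) phase, and at larger S through a SNIC onto
the static-rivalry limit cycle.  The existence of the asymmetric state
at arbitrarily low S is what lets a small background input hold the
last dominant percept as a short-term memory: with pool 1 dominant the
state survives exactly while

    s1 * b * f(S - a1) + a2 > S > a1

(b the inhibition magnitude, fatigue terms folded into a, s).  Both
inequalities are checked by :func:`asymmetric_condition`; concavity of
the gain makes the no-fatigue condition scale-free, so satisfying it at
S_on implies it at every smaller positive background level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .circuit import CircuitParams, CircuitState, GainFunction, integrate
from .stimulus import BackgroundSpec, ConstantDrive, PulseSpec, two_pool_schedule

__all__ = [
    "FixedPoint",
    "RegimeScan",
    "asymmetric_condition",
    "find_fixed_points",
    "bifurcation_scan",
    "memory_region",
    "simulated_attractors",
]

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class FixedPoint:
    u: np.ndarray
    a: np.ndarray
    s: np.ndarray
    active_set: frozenset
    stability: str  # stable | unstable | marginal
    leading_eigenvalue: float
    residual: float

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def asymmetric_condition(S, a1, a2, s1, beta_mag, gain: GainFunction) -> bool:
    """Existence of the one-pool-dominant state (strict inequalities).

    ``beta_mag`` is the inhibition magnitude (positive); ``a1``/``a2``
    the effective local-fatigue levels of the dominant/suppressed pool
    and ``s1`` the depression of the synapse leaving the dominant pool.
    """
    if not beta_mag > 0:
        raise ValueError("beta_mag is an inhibition magnitude (> 0)")
    return bool(s1 * beta_mag * gain(S - a1) + a2 > S) and bool(S > a1)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------


def _two_pool_coeffs(params: CircuitParams):
    if params.n_pools != 2:
        raise ValueError("equilibrium analysis is for the two-pool circuit")
    w = params.weights
    if not (w[0, 1] < 0 and w[1, 0] < 0):
        raise ValueError("off-diagonal weights must be inhibitory (negative)")
    return abs(w[0, 1]), abs(w[1, 0]), w[0, 0], w[1, 1]


def _equilibrium_s(u_pre, phi):
    """Slow-equation equilibrium of the depression variable for
    presynaptic activity u_pre."""
    return 1.0 / (1.0 + phi * u_pre)


def _fp_residual(params, S, u):
    gamma = params.local_fatigue_strength
    phi = params.nonlocal_fatigue_strength
    s = _equilibrium_s(u[None, :].repeat(2, axis=0), phi)
    arg = S + (s * params.weights) @ u - gamma * u
    return u - params.gain(arg), arg, s


def _jacobian(params, S, u):
    """Jacobian of the full (u, a, s) system at an equilibrium, gain
    slope taken one-sided from the active side at threshold kinks."""
    n = params.n_pools
    gamma = params.local_fatigue_strength
    phi = params.nonlocal_fatigue_strength
    tau_u, tau_a, tau_s = params.tau_u_ms, params.tau_a_ms, params.tau_s_ms
    _, arg, s = _fp_residual(params, S, u)
    fp = np.array([params.gain.derivative(x) if x > 0 else 0.0 for x in arg])
    marginal = bool(np.any(np.abs(arg) < 1e-12) and params.gain.variant == "hard")
    w = params.weights
    m = 2 * n + n * n
    J = np.zeros((m, m))

    def s_idx(i, j):
        return 2 * n + i * n + j

    for i in range(n):
        for j in range(n):
            J[i, j] = (-(i == j) + fp[i] * s[i, j] * w[i, j]) / tau_u
            J[i, n + j] = -(i == j) * gamma * fp[i] / tau_u
            J[i, s_idx(i, j)] = fp[i] * w[i, j] * u[j] / tau_u
        J[n + i, i] = 1.0 / tau_a
        J[n + i, n + i] = -1.0 / tau_a
        for j in range(n):
            J[s_idx(i, j), s_idx(i, j)] = -(1.0 + phi * u[j]) / tau_s
            J[s_idx(i, j), j] += -phi * s[i, j] / tau_s
    return J, marginal


def _classify(params, S, u) -> FixedPoint:
    res, arg, s = _fp_residual(params, S, u)
    J, marginal = _jacobian(params, S, u)
    eig = np.linalg.eigvals(J)
    lead = float(np.max(eig.real))
    if marginal or abs(lead) < 1e-9:
        stability = "marginal"
    else:
        stability = "stable" if lead < 0 else "unstable"
    return FixedPoint(
        u=u.copy(),
        a=u.copy(),
        s=s,
        active_set=frozenset(int(i) for i in np.flatnonzero(u > 0)),
        stability=stability,
        leading_eigenvalue=lead,
        residual=float(np.max(np.abs(res))),
    )


def _scalar_roots(fun, u_max, n_grid=800):
    grid = np.linspace(0.0, u_max, n_grid)
    vals = np.array([fun(x) for x in grid])
    roots = []
    for k in range(len(grid) - 1):
        v0, v1 = vals[k], vals[k + 1]
        if v0 == 0.0:
            roots.append(grid[k])
        elif v0 * v1 < 0:
            roots.append(brentq(fun, grid[k], grid[k + 1], xtol=1e-14))
    out = []
    for r in roots:
        if not any(abs(r - o) < 1e-9 for o in out):
            out.append(r)
    return out


def find_fixed_points(params: CircuitParams, S: float) -> list:
    """Enumerate equilibria of the two-pool circuit at static drive S.

    The slow variables are closed at their equilibria (a_i = u_i,
    s_ij = 1/(1 + phi u_j)); each activation support (neither, one, or
    both pools active) is solved by bracketed scalar root finding (plus
    a planar polish for asymmetric both-active states), solutions are
    kept only when consistent with their support, and stability is read
    off the Jacobian eigenvalues of the full (u, a, s) system.
    """
    b12, b21, w11, w22 = _two_pool_coeffs(params)
    gamma = params.local_fatigue_strength
    phi = params.nonlocal_fatigue_strength
    f = params.gain
    u_max = max(4.0, 4.0 * float(f(max(abs(S), 1.0))) + 1.0)
    points = []

    def add(u1, u2):
        u = np.array([u1, u2], dtype=float)
        res, arg, _ = _fp_residual(params, S, u)
        if np.max(np.abs(res)) > 1e-8:
            return
        for i in range(2):  # support consistency: silent pools below threshold
            if u[i] <= 1e-12 and arg[i] > 1e-9:
                return
        u = np.where(u < 1e-12, 0.0, u)
        for p in points:
            if np.allclose(p.u, u, atol=1e-7):
                return
        points.append(_classify(params, S, u))

    # -- empty support
    if float(f(S)) == 0.0:
        add(0.0, 0.0)

    # -- single-pool supports
    def one_pool(w_self, b_other):
        def g(x):
            se = _equilibrium_s(x, phi)
            return x - float(f(S + w_self * se * x - gamma * x))

        return [x for x in _scalar_roots(g, u_max) if x > 1e-12]

    for u1 in one_pool(w11, b21):
        add(u1, 0.0)
    for u2 in one_pool(w22, b12):
        add(0.0, u2)

    # -- both active: symmetric branch
    def sym(x):
        se = _equilibrium_s(x, phi)
        return x - float(f(S + (w11 - b12) * se * x - gamma * x))

    for x in _scalar_roots(sym, u_max):
        if x > 1e-12:
            add(x, x)

    # -- both active: asymmetric pairs (planar root from grid starts)
    def planar(v):
        u = np.abs(v)
        r, _, _ = _fp_residual(params, S, u)
        return r

    starts = [
        (x, y)
        for x in np.linspace(0.05, u_max, 7)
        for y in np.linspace(0.05, u_max, 7)
        if x != y
    ]
    for x0 in starts:
        sol = root(planar, x0=np.array(x0), method="hybr", tol=1e-13)
        if sol.success:
            u = np.abs(sol.x)
            if np.all(u > 1e-10):
                add(u[0], u[1])

    points.sort(key=lambda p: (len(p.active_set), -(p.u[0] - p.u[1])))
    return points


def simulated_attractors(
    params: CircuitParams,
    S: float,
    n_inits: int = 100,
    seed: int = 0,
    t_final_factor: float = 60.0,
    dt: float | None = None,
):
    """Long-run endpoints from seeded random initial conditions (the
    simulation oracle for the fixed-point solver)."""
    rng = np.random.default_rng(seed)
    horizon = t_final_factor * max(params.tau_a_ms, params.tau_s_ms)
    drive = ConstantDrive(np.full(params.n_pools, S))
    endpoints = []
    for _ in range(n_inits):
        u0 = rng.uniform(0.0, 1.5, params.n_pools)
        a0 = rng.uniform(0.0, 1.0, params.n_pools)
        s0 = rng.uniform(0.3, 1.0, (params.n_pools, params.n_pools))
        traj = integrate(
            params,
            CircuitState(u0, a0, s0),
            drive,
            (0.0, horizon),
            dt=dt,
            record_every=200,
        )
        tail = traj.u[int(0.9 * len(traj.times)):]
        endpoints.append(
            {
                "u_final": traj.u[-1],
                "a_final": traj.a[-1],
                "s_final": traj.s[-1],
                "settled": bool(np.max(tail.max(0) - tail.min(0)) < 1e-6),
            }
        )
    return endpoints


# ---------------------------------------------------------------------------
# limit cycles and the regime scan
# ---------------------------------------------------------------------------


def _detect_limit_cycle(params, S, dt=None, n_tau=50.0, transient_tau=10.0):
    """Simulate and count dominance switches: at least four switches with
    period CV < 10% counts as a limit cycle."""
    tau_slow = max(params.tau_a_ms, params.tau_s_ms)
    drive = ConstantDrive(np.full(params.n_pools, S))
    f_S = float(params.gain(S)) if S > 0 else 0.1
    u0 = np.array([max(0.9 * f_S, 0.05), 0.01])
    state = CircuitState(u0, np.zeros(2), np.ones((2, 2)))
    traj = integrate(
        params,
        state,
        drive,
        (0.0, (transient_tau + n_tau) * tau_slow),
        dt=dt,
        record_every=20,
    )
    keep = traj.times >= transient_tau * tau_slow
    d = traj.u[keep, 0] - traj.u[keep, 1]
    t = traj.times[keep]
    amp = float(np.max(np.abs(d))) if len(d) else 0.0
    if amp < 1e-6:
        return {"present": False, "period_ms": np.nan, "amplitude": amp}
    thr = 0.2 * amp
    sign = 0
    crossings = []
    for i in range(len(d)):
        if d[i] > thr and sign <= 0:
            if sign < 0:
                crossings.append(t[i])
            sign = 1
        elif d[i] < -thr and sign >= 0:
            if sign > 0:
                crossings.append(t[i])
            sign = -1
    if len(crossings) < 4:
        return {"present": False, "period_ms": np.nan, "amplitude": amp}
    half_periods = np.diff(crossings)
    cv = float(np.std(half_periods) / np.mean(half_periods))
    if cv >= 0.10:
        return {"present": False, "period_ms": np.nan, "amplitude": amp}
    return {
        "present": True,
        "period_ms": float(2.0 * np.mean(half_periods)),
        "amplitude": amp,
    }


@dataclass
class RegimeScan:
    S_grid: np.ndarray
    fixed_points: list  # list (per S) of FixedPoint lists
    limit_cycles: list  # list (per S) of dicts
    regimes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for S, fps, lc, reg in zip(
            self.S_grid, self.fixed_points, self.limit_cycles, self.regimes
        ):
            for k, p in enumerate(fps):
                rows.append(
                    {
                        "S": S,
                        "branch": k,
                        "u1": p.u[0],
                        "u2": p.u[1],
                        "u1_minus_u2": p.u[0] - p.u[1],
                        "stability": p.stability,
                        "cycle_present": lc["present"],
                        "cycle_period_ms": lc["period_ms"],
                        "regime": reg,
                    }
                )
        return pd.DataFrame(rows)

    def regime_at(self, S: float) -> str:
        idx = int(np.argmin(np.abs(self.S_grid - S)))
        return self.regimes[idx]


def bifurcation_scan(params: CircuitParams, S_grid, dt=None) -> RegimeScan:
    """u1 - u2 regime scan over static drive S.

    Per grid point: support-enumerated fixed points, simulated
    limit-cycle detection, and a regime label (symmetric /
    winner-take-all / rivalry / bistable).
    """
    S_grid = np.asarray(S_grid, dtype=float)
    if np.any(np.diff(S_grid) <= 0):
        raise ValueError("S grid must be strictly increasing")
    fixed_points, cycles, regimes = [], [], []
    for S in S_grid:
        fps = find_fixed_points(params, S)
        stable_asym = [
            p for p in fps if p.stable and abs(p.u[0] - p.u[1]) > 1e-8
        ]
        stable_sym = [
            p for p in fps if p.stable and abs(p.u[0] - p.u[1]) <= 1e-8
        ]
        if stable_asym:
            lc = {"present": False, "period_ms": np.nan, "amplitude": np.nan}
        else:
            lc = _detect_limit_cycle(params, S, dt=dt)
        if lc["present"]:
            regime = "bistable" if stable_sym else "rivalry"
        elif stable_asym:
            regime = "winner-take-all"
        else:
            regime = "symmetric"
        fixed_points.append(fps)
        cycles.append(lc)
        regimes.append(regime)
    return RegimeScan(S_grid, fixed_points, cycles, regimes)


def memory_region(
    params: CircuitParams,
    pulse: PulseSpec,
    background: BackgroundSpec,
    T_frame_grid,
    horizon_frames: int = 100,
    dt=None,
    initial_bias: float = 1e-4,
) -> pd.DataFrame:
    """Alternation map of the intermittent protocol over frame intervals.

    For each T_frame the pulse train runs from rest (with a tiny
    symmetry-breaking activity bias on the first pool) for
    ``horizon_frames`` transitions; a row reports whether any percept
    alternation occurred.  The memory-region boundary is the largest
    alternating T_frame in the grid.
    """
    from .readout import dominance_records, dominant_labels

    rows = []
    for T_frame in T_frame_grid:
        sched = two_pool_schedule(float(T_frame), horizon_frames, pulse, background)
        state0 = CircuitState.rested(2)
        state0.u[0] = initial_bias
        traj = integrate(
            params,
            state0,
            sched,
            sched.span,
            dt=dt,
            record_every=5,
        )
        trace = dominant_labels(traj, sched.decision_times)
        records = dominance_records(trace)
        n_switches = sum(1 for r in records if not r.censored)
        rows.append(
            {
                "T_frame_ms": float(T_frame),
                "alternated": n_switches > 0,
                "n_switches": n_switches,
            }
        )
    return pd.DataFrame(rows)
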