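"""Rate-model dynamics of the canonical mutual-inhibition cortical circuit.

The circuit is a network of ``N`` neuronal pools with activity ``u_i``,
a local (within-pool) fatigue variable ``a_i`` modelling spike-frequency
adaptation or recurrent synaptic depression, and a nonlocal fatigue
variable ``s_ij`` modelling activity-dependent depression of the synapse
from pool ``j`` onto pool ``i``:

    tau_u * du_i/dt  = -u_i + f(S_i + sum_j s_ij * beta_ij * u_j - gamma * a_i)
    tau_a * da_i/dt  = -a_i + u_i
    tau_s * ds_ij/dt = 1 - s_ij - phi * s_ij * u_j

``f`` is a threshold gain function (square root above threshold, zero
below), ``beta_ij`` a signed synaptic weight (negative = inhibition),
``gamma`` and ``phi`` the local and nonlocal fatigue strengths, and
``S_i(t)`` the external drive.  Times are in milliseconds throughout the
public interface; ``tau_u`` merely sets the fast time scale (the flow
field is invariant under rescaling time so that ``tau_u`` = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly by every integration
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


__all__ = [
    "GainFunction",
    "CircuitParams",
    "CircuitState",
    "Trajectory",
    "derivatives",
    "integrate",
    "build_quartet",
    "build_two_pool",
    "QUARTET_LABELS",
    "TWO_POOL_LABELS",
]

QUARTET_LABELS = ("V+", "V-", "H+", "H-")
TWO_POOL_LABELS = ("H", "V")


# ---------------------------------------------------------------------------
# gain function
# ---------------------------------------------------------------------------

_GAIN_HARD = 0
_GAIN_SMOOTHED = 1


@dataclass(frozen=True)
class GainFunction:
    """Threshold gain: square root of the positive part of the argument.

    variant "hard" is exactly ``sqrt(max(x, 0))``.  variant "smoothed"
    replaces the infinite slope at threshold by a concave quadratic on
    ``[0, smoothing_scale]`` that joins ``sqrt`` with matching value and
    slope; it converges pointwise to the hard variant as the scale goes
    to zero.  Both variants are non-decreasing, zero at and below
    threshold, and concave for positive argument.
    """

    variant: str = "hard"
    smoothing_scale: float = 0.0

    def __post_init__(self):
        if self.variant not in ("hard", "smoothed"):
            raise ValueError(f"unknown gain variant: {self.variant!r}")
        if self.variant == "smoothed" and not self.smoothing_scale > 0:
            raise ValueError("smoothed gain requires smoothing_scale > 0")

    @property
    def _kind(self) -> int:
        return _GAIN_HARD if self.variant == "hard" else _GAIN_SMOOTHED

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.variant == "hard":
            return np.sqrt(np.maximum(x, 0.0))
        eps = self.smoothing_scale
        out = np.where(x >= eps, np.sqrt(np.maximum(x, eps)), 0.0)
        mid = (x > 0) & (x < eps)
        xm = np.where(mid, x, 0.0)
        out = np.where(
            mid, 1.5 * xm / math.sqrt(eps) - xm * xm / (2.0 * eps ** 1.5), out
        )
        return out if out.ndim else float(out)

    def derivative(self, x: float, side: str = "active") -> float:
        """One-sided slope.  At the threshold kink the "active" side is
        used by default (the convention for Jacobians of fixed points
        whose pools sit exactly at threshold)."""
        if x < 0 or (x == 0 and side != "active"):
            return 0.0
        if self.variant == "hard":
            if x == 0:
                return math.inf
            return 0.5 / math.sqrt(x)
        eps = self.smoothing_scale
        if x >= eps:
            return 0.5 / math.sqrt(x)
        return 1.5 / math.sqrt(eps) - x / eps ** 1.5


def gain_eval(g: GainFunction, x) -> float:
    """Evaluate a gain function (total: any real argument is accepted)."""
    return g(x)


# ---------------------------------------------------------------------------
# parameters and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of an N-pool mutual-inhibition circuit.

    weights is the signed matrix ``beta_ij`` (entry [i, j] is the synapse
    from pool j onto pool i; negative = inhibition).  Fatigue time
    constants must be much slower than ``tau_u_ms`` (the model regime;
    enforced as a factor of at least 10).
    """

    n_pools: int
    weights: np.ndarray
    local_fatigue_strength: float  # gamma
    nonlocal_fatigue_strength: float  # phi
    tau_u_ms: float = 10.0
    tau_a_ms: float = 2000.0
    tau_s_ms: float = 2000.0
    gain: GainFunction = field(default_factory=GainFunction)
    pool_labels: tuple = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.n_pools, self.n_pools):
            raise ValueError(
                f"weights shape {w.shape} inconsistent with n_pools={self.n_pools}"
            )
        object.__setattr__(self, "weights", w)
        if self.n_pools < 2:
            raise ValueError("need at least two pools")
        if self.local_fatigue_strength < 0 or self.nonlocal_fatigue_strength < 0:
            raise ValueError("fatigue strengths must be >= 0")
        for tau in (self.tau_u_ms, self.tau_a_ms, self.tau_s_ms):
            if not tau > 0:
                raise ValueError("time constants must be positive")
        if self.tau_a_ms < 10 * self.tau_u_ms or self.tau_s_ms < 10 * self.tau_u_ms:
            raise ValueError(
                "fatigue time constants must be much slower than tau_u "
                "(at least a factor of 10)"
            )
        labels = tuple(self.pool_labels) or tuple(str(i) for i in range(self.n_pools))
        if len(labels) != self.n_pools:
            raise ValueError("pool_labels length mismatch")
        object.__setattr__(self, "pool_labels", labels)

    def with_gain(self, gain: GainFunction) -> "CircuitParams":
        return replace(self, gain=gain)


@dataclass
class CircuitState:
    """Instantaneous state (u, a, s) of the circuit."""

    u: np.ndarray
    a: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = self.u.shape[0]
        if self.a.shape != (n,) or self.s.shape != (n, n):
            raise ValueError("inconsistent state dimensions")

    @classmethod
    def rested(cls, n_pools: int) -> "CircuitState":
        """Fully rested state: zero activity, zero local fatigue,
        nonlocal fatigue (synaptic resources) at one."""
        return cls(
            u=np.zeros(n_pools), a=np.zeros(n_pools), s=np.ones((n_pools, n_pools))
        )

    def copy(self) -> "CircuitState":
        return CircuitState(self.u.copy(), self.a.copy(), self.s.copy())

    def validate(self):
        if np.any(self.u < 0) or np.any(self.a < 0):
            raise ValueError("u and a must be nonnegative")
        if np.any(self.s <= 0) or np.any(self.s > 1):
            raise ValueError("s must lie in (0, 1]")


@dataclass
class Trajectory:
    """Recorded integration output on a strictly increasing time grid (ms)."""

    times: np.ndarray  # (T,)
    u: np.ndarray  # (T, N)
    a: np.ndarray  # (T, N)
    s: np.ndarray  # (T, N, N)
    drive: np.ndarray  # (T, N) realized S_i at each recorded time
    pool_labels: tuple = ()

    def state_at(self, index: int) -> CircuitState:
        return CircuitState(self.u[index], self.a[index], self.s[index])

    def index_at_time(self, t_ms: float) -> int:
        i = int(np.searchsorted(self.times, t_ms, side="right") - 1)
        return max(0, min(i, len(self.times) - 1))

    @property
    def final_state(self) -> CircuitState:
        return self.state_at(-1)

    def to_frame(self):
        """Tidy long-format DataFrame (time, pool, u, a)."""
        import pandas as pd

        n = self.u.shape[1]
        labels = self.pool_labels or tuple(str(i) for i in range(n))
        return pd.DataFrame(
            {
                "time_ms": np.repeat(self.times, n),
                "pool": np.tile(np.asarray(labels, dtype=object), len(self.times)),
                "u": self.u.ravel(),
                "a": self.a.ravel(),
                "drive": self.drive.ravel(),
            }
        )

    def s_frame(self):
        """Long-format nonlocal-fatigue entries (time, post, pre, s)."""
        import pandas as pd

        n = self.u.shape[1]
        labels = np.asarray(
            self.pool_labels or tuple(str(i) for i in range(n)), dtype=object
        )
        tt = np.repeat(self.times, n * n)
        post = np.tile(np.repeat(labels, n), len(self.times))
        pre = np.tile(np.tile(labels, n), len(self.times))
        return pd.DataFrame(
            {"time_ms": tt, "post": post, "pre": pre, "s": self.s.ravel()}
        )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def derivatives(state: CircuitState, drive: np.ndarray, params: CircuitParams):
    """Time derivatives (du, da, ds) of the circuit equations, in 1/ms."""
    drive = np.asarray(drive, dtype=float)
    if drive.shape != state.u.shape or state.u.shape[0] != params.n_pools:
        raise ValueError("dimension mismatch between state, drive, and params")
    u, a, s = state.u, state.a, state.s
    arg = drive + (s * params.weights) @ u - params.local_fatigue_strength * a
    du = (-u + params.gain(arg)) / params.tau_u_ms
    da = (-a + u) / params.tau_a_ms
    ds = (1.0 - s - params.nonlocal_fatigue_strength * s * u[None, :]) / params.tau_s_ms
    return du, da, ds


@njit(cache=False)
def _gain_kernel(x, kind, eps):  # pragma: no cover - numba-compiled
    if x <= 0.0:
        return 0.0
    if kind == 0 or x >= eps:
        return math.sqrt(x)
    return 1.5 * x / math.sqrt(eps) - x * x / (2.0 * eps ** 1.5)


@njit(cache=False)
def _rk4_loop(
    u,
    a,
    s,
    drives,
    dt,
    weights,
    gamma,
    phi,
    tau_u,
    tau_a,
    tau_s,
    gain_kind,
    gain_eps,
    record_every,
    u_out,
    a_out,
    s_out,
):  # pragma: no cover - numba-compiled
    n = u.shape[0]
    n_steps = drives.shape[0]
    du = np.empty(n)
    da = np.empty(n)
    ds = np.empty((n, n))
    ku = np.empty((4, n))
    ka = np.empty((4, n))
    ks = np.empty((4, n, n))
    ut = np.empty(n)
    at = np.empty(n)
    st = np.empty((n, n))
    rec = 0
    u_out[0] = u
    a_out[0] = a
    s_out[0] = s
    for step in range(n_steps):
        drive = drives[step]
        for stage in range(4):
            if stage == 0:
                for i in range(n):
                    ut[i] = u[i]
                    at[i] = a[i]
                    for j in range(n):
                        st[i, j] = s[i, j]
            elif stage == 1 or stage == 2:
                h = 0.5 * dt
                for i in range(n):
                    ut[i] = u[i] + h * ku[stage - 1, i]
                    at[i] = a[i] + h * ka[stage - 1, i]
                    for j in range(n):
                        st[i, j] = s[i, j] + h * ks[stage - 1, i, j]
            else:
                for i in range(n):
                    ut[i] = u[i] + dt * ku[2, i]
                    at[i] = a[i] + dt * ka[2, i]
                    for j in range(n):
                        st[i, j] = s[i, j] + dt * ks[2, i, j]
            for i in range(n):
                acc = drive[i] - gamma * at[i]
                for j in range(n):
                    acc += st[i, j] * weights[i, j] * ut[j]
                du[i] = (-ut[i] + _gain_kernel(acc, gain_kind, gain_eps)) / tau_u
                da[i] = (-at[i] + ut[i]) / tau_a
                for j in range(n):
                    ds[i, j] = (1.0 - st[i, j] - phi * st[i, j] * ut[j]) / tau_s
            for i in range(n):
                ku[stage, i] = du[i]
                ka[stage, i] = da[i]
                for j in range(n):
                    ks[stage, i, j] = ds[i, j]
        for i in range(n):
            u[i] += dt / 6.0 * (ku[0, i] + 2 * ku[1, i] + 2 * ku[2, i] + ku[3, i])
            if u[i] < 0.0:
                u[i] = 0.0
            a[i] += dt / 6.0 * (ka[0, i] + 2 * ka[1, i] + 2 * ka[2, i] + ka[3, i])
            if a[i] < 0.0:
                a[i] = 0.0
            for j in range(n):
                s[i, j] += dt / 6.0 * (
                    ks[0, i, j] + 2 * ks[1, i, j] + 2 * ks[2, i, j] + ks[3, i, j]
                )
                if s[i, j] > 1.0:
                    s[i, j] = 1.0
        if (step + 1) % record_every == 0:
            rec += 1
            u_out[rec] = u
            a_out[rec] = a
            s_out[rec] = s
    return rec


def integrate(
    params: CircuitParams,
    state0: CircuitState,
    drive_fn,
    t_span,
    dt: float | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Integrate the circuit with fixed-step RK4.

    drive_fn maps a time (ms) to the length-N drive vector; it is
    evaluated once per step and held constant across the step (drives in
    this model are piecewise-constant square waves, and white background
    noise is by construction redrawn once per step).  Objects exposing a
    vectorized ``drive_array(times)`` are used directly.

    dt defaults to ``tau_u_ms / 20`` and must not exceed ``tau_u_ms / 10``.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    if dt is None:
        dt = params.tau_u_ms / 20.0
    if dt > params.tau_u_ms / 10.0 + 1e-12:
        raise ValueError(f"dt={dt} too large; require dt <= tau_u/10 = {params.tau_u_ms / 10}")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")

    n_steps = int(math.ceil((t1 - t0) / dt - 1e-9))
    # round up to a whole number of recording intervals so the endpoint
    # is always part of the returned trajectory
    n_steps = ((n_steps + record_every - 1) // record_every) * record_every
    step_times = t0 + dt * np.arange(n_steps)
    if hasattr(drive_fn, "drive_array"):
        drives = np.asarray(drive_fn.drive_array(step_times), dtype=float)
    else:
        drives = np.empty((n_steps, params.n_pools))
        for k, t in enumerate(step_times):
            drives[k] = drive_fn(t)
    if drives.shape != (n_steps, params.n_pools):
        raise ValueError("drive function returned wrong shape")

    n_rec = n_steps // record_every + 1
    u_out = np.empty((n_rec, params.n_pools))
    a_out = np.empty((n_rec, params.n_pools))
    s_out = np.empty((n_rec, params.n_pools, params.n_pools))
    state = state0.copy()
    state.validate()

    last = _rk4_loop(
        state.u,
        state.a,
        state.s,
        drives,
        float(dt),
        params.weights,
        float(params.local_fatigue_strength),
        float(params.nonlocal_fatigue_strength),
        float(params.tau_u_ms),
        float(params.tau_a_ms),
        float(params.tau_s_ms),
        params.gain._kind,
        float(params.gain.smoothing_scale),
        int(record_every),
        u_out,
        a_out,
        s_out,
    )
    u_out = u_out[: last + 1]
    a_out = a_out[: last + 1]
    s_out = s_out[: last + 1]
    if not (np.all(np.isfinite(u_out)) and np.all(np.isfinite(a_out))):
        raise RuntimeError(
            "integration produced non-finite state; "
            "check parameters (weights/gain) for runaway excitation"
        )

    rec_times = t0 + dt * record_every * np.arange(last + 1)
    rec_idx = np.minimum(record_every * np.arange(last + 1), n_steps - 1)
    return Trajectory(
        times=rec_times,
        u=u_out,
        a=a_out,
        s=s_out,
        drive=drives[rec_idx],
        pool_labels=params.pool_labels,
    )


# ---------------------------------------------------------------------------
# network constructors
# ---------------------------------------------------------------------------


def build_quartet(
    inhibition: float,
    like_orientation: float,
    like_direction: float,
    *,
    self_excitation: float = 0.0,
    local_fatigue_strength: float = 0.0,
    nonlocal_fatigue_strength: float = 0.0,
    tau_u_ms: float = 10.0,
    tau_a_ms: float = 2000.0,
    tau_s_ms: float = 2000.0,
    gain: GainFunction | None = None,
) -> CircuitParams:
    """Four-pool circuit for the ambiguous-quartet illusion.

    Pools are labelled V+, V-, H+, H- (orientation x rotation
    direction).  Competing percept pairs (V+/H-, V-/H+) inhibit each
    other; like-orientation pairs (V+/V-, H+/H-) and like-direction
    pairs (V+/H+, V-/H-) are coupled by positive weights, which biases
    the circuit toward orientation-persistent orbits with a direction
    flip on every frame transition.  The weight matrix is invariant
    under the stimulus symmetry group (swap H/V, swap +/-).
    """
    if not inhibition > 0:
        raise ValueError("competing-pair inhibition magnitude must be positive")
    if like_orientation < 0 or like_direction < 0:
        raise ValueError("like-pair weights must be nonnegative (excitatory)")
    if like_orientation == 0 and like_direction == 0:
        import warnings

        warnings.warn(
            "zero like-pair weights: degenerate quartet with no orbit bias",
            stacklevel=2,
        )
    # index order V+=0, V-=1, H+=2, H-=3
    w = np.zeros((4, 4))
    for i, j in ((0, 1), (2, 3)):
        w[i, j] = w[j, i] = like_orientation
    for i, j in ((0, 2), (1, 3)):
        w[i, j] = w[j, i] = like_direction
    for i, j in ((0, 3), (1, 2)):
        w[i, j] = w[j, i] = -inhibition
    np.fill_diagonal(w, self_excitation)
    return CircuitParams(
        n_pools=4,
        weights=w,
        local_fatigue_strength=local_fatigue_strength,
        nonlocal_fatigue_strength=nonlocal_fatigue_strength,
        tau_u_ms=tau_u_ms,
        tau_a_ms=tau_a_ms,
        tau_s_ms=tau_s_ms,
        gain=gain or GainFunction(),
        pool_labels=QUARTET_LABELS,
    )


def build_two_pool(
    inhibition: float,
    *,
    self_excitation: float = 0.0,
    local_fatigue_strength: float = 0.0,
    nonlocal_fatigue_strength: float = 0.0,
    tau_u_ms: float = 10.0,
    tau_a_ms: float = 2000.0,
    tau_s_ms: float = 2000.0,
    gain: GainFunction | None = None,
) -> CircuitParams:
    """Reduced two-pool circuit (orientation pools H, V).

    Obtained from the quartet by averaging over the fast direction
    oscillation; the like-pair excitation is subsumed within each pool
    (optionally re-exposed as recurrent ``self_excitation``, which is
    what the persistent-activity regime requires).  ``inhibition`` is
    the magnitude of the mutual inhibitory weight (must be positive: a
    non-inhibitory pair is not a rivalry circuit).
    """
    if not inhibition > 0:
        raise ValueError("mutual inhibition magnitude must be positive")
    w = np.array(
        [[self_excitation, -inhibition], [-inhibition, self_excitation]], dtype=float
    )
    return CircuitParams(
        n_pools=2,
        weights=w,
        local_fatigue_strength=local_fatigue_strength,
        nonlocal_fatigue_strength=nonlocal_fatigue_strength,
        tau_u_ms=tau_u_ms,
        tau_a_ms=tau_a_ms,
        tau_s_ms=tau_s_ms,
        gain=gain or GainFunction(),
        pool_labels=TWO_POOL_LABELS,
    )
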