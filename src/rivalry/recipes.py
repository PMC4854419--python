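"""Bundled experiments: the standard runs behind the package's figures
and acceptance checks, shared by the CLI and the test suite.

Deterministic fixed-background runs start from the rested state with a
tiny activity bias (1e-4) on the first pool: the symmetric manifold is
an exact invariant of the noiseless dynamics, so some seed asymmetry is
needed to stand in for the fluctuation that breaks the first
winner-take-all competition in a real circuit.  The bias is far below
every activity scale in the model and only selects which pool wins the
first transition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circuit import CircuitParams, CircuitState, integrate
from .equilibria import bifurcation_scan, memory_region
from .profiles import Profile, get_profile, paper_like_local, paper_like_nonlocal
from .readout import (
    dominance_records,
    dominant_labels,
    habituation_curve,
    records_to_frame,
    sweep_dynamic_L4,
)
from .stimulus import FrameSequence, quartet_schedule, two_pool_schedule
from .survival import fit_cox_mixed, records_from_reports, synth_reports

__all__ = [
    "rested_biased",
    "run_intermittent",
    "dynamic_l4_recipe",
    "habituation_recipe",
    "bifurcation_recipe",
    "memory_region_recipe",
    "survival_recovery_recipe",
    "RECIPES",
    "run_recipe",
]

DEFAULT_BIAS = 1e-4


def rested_biased(n_pools: int, bias: float = DEFAULT_BIAS,
                  pool: int = 0) -> CircuitState:
    state = CircuitState.rested(n_pools)
    state.u[pool] = bias
    return state


def run_intermittent(
    params: CircuitParams,
    profile: Profile,
    T_frame_ms: float,
    n_frames: int,
    *,
    background=None,
    bias: float = DEFAULT_BIAS,
    dt=None,
    record_every: int = 10,
):
    """One pulse-train run from (biased) rest: trajectory, percept trace
    and dominance records."""
    bg = background if background is not None else profile.background()
    if params.n_pools == 4:
        sched = quartet_schedule(
            FrameSequence(T_frame_ms, n_frames), profile.pulse(), bg
        )
    else:
        sched = two_pool_schedule(T_frame_ms, n_frames, profile.pulse(), bg)
    traj = integrate(
        params,
        rested_biased(params.n_pools, bias),
        sched,
        sched.span,
        dt=dt,
        record_every=record_every,
    )
    trace = dominant_labels(traj, sched.decision_times)
    return traj, trace, dominance_records(trace)


def dynamic_l4_recipe(profile: Profile | None = None, horizon_frames: int = 150,
                      include_no_alternation_point: bool = True) -> pd.DataFrame:
    """Mean dominance duration versus frame interval for a profile's
    calibrated grid (optionally extended past the alternation boundary)."""
    profile = profile or paper_like_local()
    grid = list(profile.T_frame_grid)
    if include_no_alternation_point and np.isfinite(profile.T_frame_no_alternation):
        grid.append(profile.T_frame_no_alternation)

    def make(T, n):
        return two_pool_schedule(T, n, profile.pulse(), profile.background())

    out = sweep_dynamic_L4(
        profile.params, make, grid, horizon_frames, state0=rested_biased(2)
    )
    out["profile"] = profile.name
    return out


def habituation_recipe(T_frame_ms: float = 260.0, n_frames: int = 120) -> pd.DataFrame:
    """Epoch curves for the rested local- and nonlocal-fatigue models
    (opposite first-epoch behavior)."""
    frames_ = []
    for prof in (paper_like_local(), paper_like_nonlocal()):
        _, _, records = run_intermittent(
            prof.params, prof, T_frame_ms, n_frames
        )
        curve = habituation_curve(records)
        curve["fatigue"] = (
            "local" if prof.params.local_fatigue_strength > 0 else "nonlocal"
        )
        frames_.append(curve)
    return pd.concat(frames_, ignore_index=True)


def bifurcation_recipe(profile: Profile | None = None, S_min=-0.05, S_max=0.45,
                       n_grid: int = 21) -> pd.DataFrame:
    """Regime scan of the two-pool circuit over static drive S."""
    profile = profile or paper_like_nonlocal()
    scan = bifurcation_scan(profile.params, np.linspace(S_min, S_max, n_grid))
    df = scan.to_frame()
    df["profile"] = profile.name
    return df


def memory_region_recipe(profile: Profile | None = None,
                         T_frame_grid=None, horizon_frames: int = 120) -> pd.DataFrame:
    profile = profile or paper_like_local()
    if T_frame_grid is None:
        lo = min(profile.T_frame_grid)
        hi = profile.T_frame_no_alternation
        if not np.isfinite(hi):
            hi = 2.0 * max(profile.T_frame_grid)
        T_frame_grid = np.linspace(lo, hi, 7)
    out = memory_region(
        profile.params,
        profile.pulse(),
        profile.background(),
        T_frame_grid,
        horizon_frames=horizon_frames,
    )
    out["profile"] = profile.name
    return out


def survival_recovery_recipe(
    n_replicates: int = 20,
    seed: int = 0,
    effect: str = "T_frame",
    log_hr: float | None = None,
    frailty_variance: float = 0.05,
    n_subjects: int = 10,
    blocks=((300, 2), (350, 2), (400, 2), (450, 2)),
    backend: str = "auto",
) -> pd.DataFrame:
    """Parameter-recovery simulation: datasets generated with a known
    log-hazard coefficient on one covariate, refit by the Cox stage."""
    if log_hr is None:
        log_hr = np.log(0.996) if effect == "T_frame" else np.log(1.024)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        ds = synth_reports(
            n_subjects=n_subjects,
            blocks=blocks,
            tframe_log_hr=log_hr if effect == "T_frame" else 0.0,
            epoch_log_hr=log_hr if effect == "epoch" else 0.0,
            frailty_variance=frailty_variance,
            seed=rep_seed,
        )
        records = records_from_reports(ds)
        fit = fit_cox_mixed(records, effect, backend=backend)
        rows.append(
            {
                "replicate": rep,
                "true_log_hr": log_hr,
                "coef": fit.coef,
                "se": fit.se,
                "within_2se": abs(fit.coef - log_hr) <= 2 * fit.se,
                "n_events": fit.n_events,
            }
        )
    return pd.DataFrame(rows)


RECIPES = {
    "dynamic-L4": dynamic_l4_recipe,
    "habituation": habituation_recipe,
    "bifurcation": bifurcation_recipe,
    "memory-region": memory_region_recipe,
    "survival-recovery": survival_recovery_recipe,
}


def run_recipe(name: str, **kwargs) -> pd.DataFrame:
    try:
        fn = RECIPES[name]
    except KeyError:
        raise KeyError(
            f"unknown recipe {name!r}; available: {sorted(RECIPES)}"
        ) from None
    return fn(**kwargs)
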