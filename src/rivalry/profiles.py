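"""Named parameter profiles.

The circuit equations leave the weight/fatigue/drive constants free; the
profiles below were fixed once by a numerical regime search and are the
package defaults for simulations, tests, and recipes.  The shared
"paper-like" base (mutual inhibition 1.5, fatigue time constants 2 s,
tau_u 10 ms, pulse width 60 ms) comes in a local-fatigue and a
nonlocal-fatigue member:

* ``paper_like_local``  — spike-frequency-adaptation-style fatigue
  (gamma = 0.15).  Pulsed on-states are winner-take-all; switching is
  release-driven (the dominant pool's fatigue crosses the background
  level S_off = 0.02); shows intermittent rivalry with dynamic L4 over
  frame intervals of roughly 180-340 ms, a no-alternation region
  beyond ~380 ms, indefinite off-state memory, and habituation
  (first epochs longest).
* ``paper_like_nonlocal`` — cross-pool synaptic depression
  (phi = 5.5).  Switching is escape-driven, the first rested epoch is
  *shorter* than later ones, and the static-rivalry limit-cycle window
  of the constant-drive circuit (between the winner-take-all phase and
  high-drive fusion) contains the pulse amplitude S_on = 0.2 itself,
  so the same input level that drives intermittent rivalry produces
  static rivalry when held on continuously.
* ``static_rivalry_local`` — a classic strong-adaptation operating
  point (gamma = 0.4, inhibition 1.2) whose constant-drive state at
  S = 1 is the static-rivalry limit cycle.

Quartet profiles add the like-orientation / like-direction excitatory
biases on top of the same constants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit import CircuitParams, build_quartet, build_two_pool
from .stimulus import BackgroundSpec, PulseSpec

__all__ = [
    "Profile",
    "paper_like_local",
    "paper_like_nonlocal",
    "static_rivalry_local",
    "persistent_activity",
    "paper_like_quartet",
    "get_profile",
    "PROFILES",
]


@dataclass(frozen=True)
class Profile:
    """A circuit plus the stimulus constants it was calibrated with."""

    name: str
    params: CircuitParams
    S_on: float
    S_off: float
    pulse_width_ms: float
    # frame-interval grid (ms) over which dynamic L4 is exhibited, and a
    # frame interval safely beyond the no-alternation boundary
    T_frame_grid: tuple
    T_frame_no_alternation: float
    # static drive at which the constant-input circuit shows a rivalry
    # limit cycle (None: outside every scanned window)
    S_static_rivalry: float | None = None

    def pulse(self, width_ms: float | None = None) -> PulseSpec:
        return PulseSpec(self.S_on, width_ms or self.pulse_width_ms)

    def background(self, mode: str = "fixed", sigma: float | None = None,
                   seed: int | None = None) -> BackgroundSpec:
        if mode == "fixed":
            return BackgroundSpec("fixed", S_off=self.S_off)
        if mode == "zero":
            return BackgroundSpec("zero")
        return BackgroundSpec("gaussian", sigma=sigma or 0.03, seed=seed)


def paper_like_local() -> Profile:
    return Profile(
        name="paper-like-local",
        params=build_two_pool(
            1.5,
            local_fatigue_strength=0.15,
            tau_a_ms=2000.0,
            tau_u_ms=10.0,
        ),
        S_on=0.5,
        S_off=0.02,
        pulse_width_ms=60.0,
        T_frame_grid=(180.0, 220.0, 260.0, 300.0, 340.0),
        T_frame_no_alternation=420.0,
        S_static_rivalry=None,
    )


def paper_like_nonlocal() -> Profile:
    return Profile(
        name="paper-like-nonlocal",
        params=build_two_pool(
            1.5,
            nonlocal_fatigue_strength=5.5,
            tau_s_ms=2000.0,
            tau_u_ms=10.0,
        ),
        S_on=0.2,
        S_off=0.002,
        pulse_width_ms=60.0,
        T_frame_grid=(180.0, 260.0, 340.0, 420.0),
        T_frame_no_alternation=float("nan"),
        S_static_rivalry=0.2,
    )


def static_rivalry_local() -> Profile:
    return Profile(
        name="static-rivalry-local",
        params=build_two_pool(
            1.2,
            local_fatigue_strength=0.4,
            tau_a_ms=2000.0,
            tau_u_ms=10.0,
        ),
        S_on=1.0,
        S_off=0.02,
        pulse_width_ms=60.0,
        T_frame_grid=(),
        T_frame_no_alternation=float("nan"),
        S_static_rivalry=1.0,
    )


def persistent_activity() -> Profile:
    """Reciprocal-excitation bistability: within a critical window of
    self-excitation an excited pool holds elevated activity at zero
    drive (and a hard reset to zero stays at zero)."""
    return Profile(
        name="persistent-activity",
        params=build_two_pool(
            1.5,
            self_excitation=1.05,
            local_fatigue_strength=0.0,
            tau_a_ms=2000.0,
            tau_u_ms=10.0,
        ),
        S_on=0.5,
        S_off=0.0,
        pulse_width_ms=60.0,
        T_frame_grid=(),
        T_frame_no_alternation=float("nan"),
    )


def paper_like_quartet() -> Profile:
    """Four-pool quartet circuit in the background-memory regime: the
    like-orientation bias exceeds the like-direction bias, so dominance
    runs are orientation-persistent with a direction flip every frame."""
    return Profile(
        name="paper-like-quartet",
        params=build_quartet(
            1.5,
            like_orientation=0.2,
            like_direction=0.05,
            local_fatigue_strength=0.15,
            tau_a_ms=2000.0,
            tau_u_ms=10.0,
        ),
        S_on=0.5,
        S_off=0.02,
        pulse_width_ms=60.0,
        T_frame_grid=(180.0, 220.0, 260.0),
        T_frame_no_alternation=340.0,
    )


PROFILES = {
    "paper-like-local": paper_like_local,
    "paper-like-nonlocal": paper_like_nonlocal,
    "paper-like-quartet": paper_like_quartet,
    "static-rivalry-local": static_rivalry_local,
    "persistent-activity": persistent_activity,
}


def get_profile(name: str) -> Profile:
    try:
        return PROFILES[name]()
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
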