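"""Time-dependent drive S_i(t) for intermittent-rivalry protocols.

The quartet stimulus is a two-frame animation; perceived motion happens
only at frame transitions, so the effective input to the pools is a
brief change-detector pulse of amplitude ``S_on`` at every transition.
Between pulses (the off-state) the pools receive nonspecific background
input ``S_off``: zero, a fixed low level, or zero-mean gaussian noise
redrawn once per integrator step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import QUARTET_LABELS, TWO_POOL_LABELS

__all__ = [
    "FrameSequence",
    "PulseSpec",
    "BackgroundSpec",
    "transition_drive",
    "drive_at_time",
    "quartet_schedule",
    "two_pool_schedule",
    "QuartetSchedule",
    "TwoPoolSchedule",
    "ConstantDrive",
]

PARITIES = ("UR-LL", "LR-UL")


@dataclass(frozen=True)
class FrameSequence:
    """A train of quartet frame transitions at interval T_frame (ms)."""

    T_frame_ms: float
    n_frames: int
    start_parity: str = "UR-LL"

    def __post_init__(self):
        if not self.T_frame_ms > 0:
            raise ValueError("T_frame must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame transition")
        if self.start_parity not in PARITIES:
            raise ValueError(f"unknown parity {self.start_parity!r}")

    def parity_at(self, k: int) -> str:
        """Parity shown before transition k (parities strictly alternate)."""
        return PARITIES[(PARITIES.index(self.start_parity) + k) % 2]


@dataclass(frozen=True)
class PulseSpec:
    """Square change-detector pulse delivered at each frame transition."""

    S_on: float
    pulse_width_ms: float

    def __post_init__(self):
        if not self.S_on > 0:
            raise ValueError("S_on must be positive")
        if not self.pulse_width_ms > 0:
            raise ValueError("pulse width must be positive")

    def validate_against(self, T_frame_ms: float):
        if self.pulse_width_ms > T_frame_ms + 1e-9:
            raise ValueError("pulse width cannot exceed the frame interval")


@dataclass
class BackgroundSpec:
    """Nonspecific background input.

    mode "zero": no background.  mode "fixed": constant ``S_off >= 0``.
    mode "gaussian": white zero-mean draws N(0, sigma^2), one per
    integrator step per pool, from a stream seeded by ``seed``.
    """

    mode: str = "zero"
    S_off: float = 0.0
    sigma: float = 0.0
    seed: int | None = None
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if self.mode not in ("zero", "fixed", "gaussian"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if self.mode == "fixed" and self.S_off < 0:
            raise ValueError("fixed S_off must be >= 0")
        if self.mode == "gaussian" and not self.sigma > 0:
            raise ValueError("gaussian background requires sigma > 0")
        self.reset()

    def reset(self):
        """Rewind the noise stream to the start (same seed, same draws)."""
        self._rng = np.random.default_rng(self.seed)

    def sample(self, shape) -> np.ndarray:
        if self.mode == "zero":
            return np.zeros(shape)
        if self.mode == "fixed":
            return np.full(shape, self.S_off)
        return self._rng.normal(0.0, self.sigma, shape)

    @property
    def mean_level(self) -> float:
        return self.S_off if self.mode == "fixed" else 0.0


def transition_drive(parity_from: str, parity_to: str) -> frozenset:
    """Quartet pools stimulated by a frame transition.

    UR-LL -> LR-UL stimulates V+ and H-; the reverse transition
    stimulates V- and H+.
    """
    for p in (parity_from, parity_to):
        if p not in PARITIES:
            raise ValueError(f"unknown parity {p!r}")
    if parity_from == parity_to:
        raise ValueError("identical parities: no transition, no drive")
    if parity_from == "UR-LL":
        return frozenset({"V+", "H-"})
    return frozenset({"V-", "H+"})


class _PulseTrain:
    """Shared machinery: pulse windows on [start, start + n*T)."""

    def __init__(self, T_frame_ms, n_frames, pulse: PulseSpec, bg: BackgroundSpec,
                 labels, start_ms=0.0):
        pulse.validate_against(T_frame_ms)
        self.T_frame_ms = float(T_frame_ms)
        self.n_frames = int(n_frames)
        self.pulse = pulse
        self.bg = bg
        self.labels = tuple(labels)
        self.start_ms = float(start_ms)

    @property
    def n_pools(self) -> int:
        return len(self.labels)

    @property
    def span(self):
        return (self.start_ms, self.start_ms + self.n_frames * self.T_frame_ms)

    @property
    def pulse_onsets(self) -> np.ndarray:
        return self.start_ms + self.T_frame_ms * np.arange(self.n_frames)

    @property
    def pulse_windows(self) -> np.ndarray:
        on = self.pulse_onsets
        return np.stack([on, on + self.pulse.pulse_width_ms], axis=1)

    @property
    def decision_times(self) -> np.ndarray:
        """End of each pulse window (where dominance is scored)."""
        return self.pulse_onsets + self.pulse.pulse_width_ms

    def _check_span(self, times):
        t0, t1 = self.span
        if np.any(times < t0 - 1e-9) or np.any(times >= t1 + 1e-9):
            raise ValueError(f"time outside the protocol span [{t0}, {t1})")

    def _pulse_mask(self, times):
        rel = (np.asarray(times, dtype=float) - self.start_ms) % self.T_frame_ms
        return rel < self.pulse.pulse_width_ms - 1e-12

    def _transition_index(self, times):
        return np.floor(
            (np.asarray(times, dtype=float) - self.start_ms) / self.T_frame_ms
        ).astype(int)

    def _pool_mask(self, times):  # (T, N) bool: which pools are pulsed
        raise NotImplementedError

    def drive_array(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        self._check_span(times)
        drive = self.bg.sample((len(times), self.n_pools))
        pulsed = self._pool_mask(times) & self._pulse_mask(times)[:, None]
        # background is nonspecific and stays on additively during pulses
        drive = drive + self.pulse.S_on * pulsed
        return drive

    def __call__(self, t) -> np.ndarray:
        return self.drive_array([t])[0]


class QuartetSchedule(_PulseTrain):
    """Quartet drive: each transition pulses the two parity-consistent pools."""

    def __init__(self, frames: FrameSequence, pulse: PulseSpec, bg: BackgroundSpec,
                 labels=QUARTET_LABELS, start_ms=0.0):
        super().__init__(frames.T_frame_ms, frames.n_frames, pulse, bg, labels,
                         start_ms)
        self.frames = frames
        masks = []
        for k in range(frames.n_frames):
            p_from = frames.parity_at(k)
            p_to = frames.parity_at(k + 1)
            driven = transition_drive(p_from, p_to)
            masks.append([lab in driven for lab in self.labels])
        self._masks = np.asarray(masks, dtype=bool)

    def driven_pools(self, k: int) -> frozenset:
        return frozenset(
            lab for lab, m in zip(self.labels, self._masks[k]) if m
        )

    def _pool_mask(self, times):
        idx = np.clip(self._transition_index(times), 0, self.n_frames - 1)
        return self._masks[idx]


class TwoPoolSchedule(_PulseTrain):
    """Reduced-model drive: both orientation pools pulsed at each transition
    (the direction oscillation is averaged out)."""

    def __init__(self, T_frame_ms, n_frames, pulse: PulseSpec, bg: BackgroundSpec,
                 labels=TWO_POOL_LABELS, start_ms=0.0):
        super().__init__(T_frame_ms, n_frames, pulse, bg, labels, start_ms)

    def _pool_mask(self, times):
        return np.ones((len(np.atleast_1d(times)), self.n_pools), dtype=bool)


class ConstantDrive:
    """Constant drive vector on an unbounded span (static stimulation or
    off-state gaps between pulse trains)."""

    def __init__(self, drive, bg: BackgroundSpec | None = None):
        self._drive = np.asarray(drive, dtype=float)
        self.bg = bg

    def drive_array(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.tile(self._drive, (len(times), 1))
        if self.bg is not None:
            out = out + self.bg.sample(out.shape)
        return out

    def __call__(self, t):
        return self.drive_array([t])[0]


def drive_at_time(t, frames: FrameSequence, pulse: PulseSpec, bg: BackgroundSpec,
                  labels=QUARTET_LABELS) -> np.ndarray:
    """Drive vector at time t for a quartet frame train (scalar front-end;
    gaussian background consumes one fresh draw per call)."""
    return QuartetSchedule(frames, pulse, bg, labels)(t)


def quartet_schedule(frames: FrameSequence, pulse: PulseSpec, bg: BackgroundSpec,
                     start_ms=0.0) -> QuartetSchedule:
    return QuartetSchedule(frames, pulse, bg, start_ms=start_ms)


def two_pool_schedule(T_frame_ms, n_frames, pulse: PulseSpec, bg: BackgroundSpec,
                      start_ms=0.0) -> TwoPoolSchedule:
    return TwoPoolSchedule(T_frame_ms, n_frames, pulse, bg, start_ms=start_ms)
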