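# Methods

## Model

The package simulates the canonical mutual-inhibition cortical circuit
for perceptual rivalry.  Each of `N` neuronal pools carries an activity
`u_i`, a local fatigue variable `a_i` (spike-frequency adaptation or
recurrent synaptic depression) and a nonlocal fatigue variable `s_ij`
(depression of the synapse from pool `j` onto pool `i`):

    tau_u du_i/dt  = -u_i + f( S_i + sum_j s_ij * beta_ij * u_j - gamma * a_i )
    tau_a da_i/dt  = -a_i + u_i
    tau_s ds_ij/dt = 1 - s_ij - phi * s_ij * u_j

`f` is a threshold gain, square root above threshold and zero below;
`beta_ij` is a signed weight (negative = inhibition); `gamma` and `phi`
set the local and nonlocal fatigue strengths; `S_i(t)` is the external
drive.  Depression applies uniformly to every connection (`phi = 0`
disables it globally).  All public times are in milliseconds.  `tau_u`
only sets the fast time scale — the flow field is invariant under
rescaling time so that `tau_u = 1` — and defaults to 10 ms; the fatigue
constants default to 2 s, the order of magnitude of adaptation and
synaptic depression, and must be at least ten times slower than
`tau_u` (the regime in which the model's analysis is valid).

Two standard networks are provided.  The four-pool *quartet* circuit
(pools V+, V-, H+, H-) represents the two orientations x two rotation
directions of ambiguous apparent motion: competing percept pairs
(V+/H-, V-/H+) inhibit each other, while like-orientation and
like-direction pairs are weakly excitatory, biasing the circuit toward
orientation-persistent orbits that flip direction on every frame.  The
reduced *two-pool* circuit (H, V) averages over the fast direction
oscillation; the like-pair excitation is absorbed into the pool (or
optionally re-exposed as recurrent self-excitation, which is what the
persistent-activity regime requires).

## Stimulus protocols

The quartet stimulus only drives the pools at frame transitions, via a
change-detecting pathway, so the drive is a square pulse train: during
an on-state the two transition-consistent pools (both pools, in the
reduced model) receive `S_on` for `pulse_width` ms; between pulses all
pools receive the nonspecific background `S_off` — zero, a fixed low
level, or zero-mean gaussian noise redrawn once per integrator step
(white noise; its effect therefore depends mildly on the step size,
which is recorded with every run).  Background remains on additively
during pulses: nonspecific input does not gate off during stimulation
and is negligible against `S_on`.  The stimulus literature fixes only
that the transient is "brief"; the pulse width is configurable and the
calibrated profiles use a fixed 60 ms pulse regardless of frame
interval, so that the per-pulse fatigue increment is constant while the
between-pulse recovery grows with the frame interval.  That choice is
what gives a clean no-alternation boundary at long frame intervals; a
pulse width proportional to the frame interval makes the per-pulse
increment grow as well and can invert the trend.

## Readout

The most active pool at the end of each pulse is the percept for that
transition (end-of-pulse is the declared decision time: the activity
imbalance is largest and quasi-stationary there; a midpoint decision
differs only in degenerate cases).  Ties retain the previous label
(hysteresis); an initial tie goes to the lowest pool index.  Quartet
labels are grouped by orientation before run-length encoding; stretches
of at least three transitions with a constant rotation direction are
the rotation percept and are excluded from orientation dominance
summaries (a single direction repeat is just an orientation switch and
is not rotation).  A dominance record is an uninterrupted run of one
orientation: its epoch (1-based order), duration `T_D` in movie frames
and a censoring flag — the final record of every run is right-censored,
matching the treatment of block ends in the human data.

Deterministic fixed-background runs start from rest with a tiny
(1e-4) activity bias on one pool.  The symmetric state is an exact
invariant manifold of the noiseless equations, so *some* asymmetry must
seed the first winner-take-all competition; the bias is orders of
magnitude below every activity scale and only selects the first winner.

## Switch mechanisms

The one-pool-dominant state of the two-pool circuit exists exactly
while `s1*b*f(S - a1) + a2 > S > a1` (inhibition magnitude `b`,
fatigue folded into `a`, `s`).  Failure of the first inequality is
*escape* (the suppressed pool overcomes weakened inhibition); failure
of the second at the background level is *release* (the dominant pool
cannot stay active on `S_off` alone).  The classifier scans the
trajectory between the decision times bracketing a switch: a release is
recorded when `gamma * a_dominant` crosses `S_off` during an off-state;
otherwise an actual takeover is classified as escape.  The operational
rule matters because under fast pulsed protocols the challenger can
escape through the on-state transient slightly before the static
inequality `s1*b*f(S_on) + a2 < S_on` is reached; requiring the static
clause would leave fast escapes unclassified.

## Equilibria and regimes

Fixed points of the two-pool system close the slow variables at their
equilibria (`a_i = u_i`, `s_ij = 1/(1 + phi*u_j)`) and enumerate the
activation supports: neither, one, or both pools active.  Each support
reduces to bracketed scalar root finding (grid scan + Brent); asymmetric
both-active states are polished by a planar Newton iteration from grid
starts.  Solutions inconsistent with their support are discarded;
stability comes from the Jacobian eigenvalues of the full `(u, a, s)`
system, with the gain slope taken one-sided from the active side at the
threshold kink (points exactly at the kink are reported "marginal").
Residual tolerance is 1e-10; the simulation oracle must match stable
points to 1e-6 in `u`.

Limit cycles are detected by simulation: 50 fatigue time constants
after a 10-constant transient, requiring at least four dominance
switches with half-period coefficient of variation under 10%.  Regime
labels per static drive `S`: *symmetric* (only symmetric attractor),
*winner-take-all* (stable asymmetric fixed points), *rivalry* (limit
cycle), *bistable* (limit cycle coexisting with a stable symmetric
state).  No general continuation is attempted (no Hopf normal forms,
no period-doubling tracking); the scan reproduces regime ordering, not
exact bifurcation coordinates.

## Calibrated profiles

The circuit's phenomenology is defined by qualitative regimes rather
than by a canonical parameter table, so the package ships profiles
fixed once by a regime search and treated as defaults everywhere:

* **paper-like-local** (`b = 1.5`, `gamma = 0.15`, `tau_a = 2 s`,
  `S_on = 0.5`, `S_off = 0.02`, pulse 60 ms).  Pulsed on-states are
  winner-take-all; switches are release-driven.  Dominance duration
  grows from ~3 to ~12 frames over frame intervals of 180-340 ms with
  no alternations beyond ~380 ms; memory is indefinite (the off-state
  fatigue equilibrium `gamma*a ≈ 0.013` sits well below `S_off`);
  rested runs habituate (first epochs longest).  The weak `gamma` is
  essential: release-driven dominance with genuine margins requires
  `gamma` of order `sqrt(S_off)`, which in turn rules out a static
  rivalry window for this member (escape at constant drive would need
  `gamma` comparable to `b`, and then the off-state fatigue equilibrium
  sits at the release threshold and dominance collapses to one frame).
* **paper-like-nonlocal** (`b = 1.5`, `phi = 5.5`, `tau_s = 2 s`,
  `S_on = 0.2`, `S_off = 0.002`, pulse 60 ms).  Switches are
  escape-driven; the first rested epoch is *shorter* than later ones;
  and the constant-drive circuit passes, with increasing `S`, from the
  symmetric phase through the pitchfork at `S = 0` into winner-take-all
  and then into a rivalry limit-cycle window that contains `S_on`
  itself, closing with a bistable stretch before high-drive fusion.
  The bifurcation recipes scan this member.
* **static-rivalry-local** (`b = 1.2`, `gamma = 0.4`, `S = 1`): the
  classic strong-adaptation static-rivalry operating point (escape
  oscillation with a ~13 s period), kept for constant-drive demos.
* **paper-like-quartet**: the local-fatigue constants plus
  like-orientation 0.2 and like-direction 0.05 biases; orientation
  dominance persists over many transitions with a direction flip each
  frame, and alternates on the tens-of-frames scale for frame
  intervals of 180-260 ms.
* **persistent-activity** (self-excitation 1.05, no fatigue):
  reciprocal-excitation bistability — an excited pool holds elevated
  activity at zero drive and a hard reset stays silent.  Kept as a
  contrast: this mechanism requires tuning the excitation into a
  critical window, unlike the background-activity memory.

The dominance-duration boundary is strongly nonlinear in the frame
interval near the no-alternation boundary (the fatigue peak approaches
the release threshold), which is why the calibrated grids stop short of
the boundary rather than straddling it.

## Numerics

Fixed-step classical Runge-Kutta with `dt = tau_u / 20` by default
(`dt <= tau_u / 10` enforced); the dynamics are non-stiff at the
model's time-scale separation and a fixed step keeps runs bit-for-bit
reproducible.  The drive is evaluated once per step and held constant
across it — drives here are piecewise-constant square waves, and the
gaussian background is *defined* as one fresh draw per step.  The gain
threshold is integrated through (the gain is continuous; no event
detection).  The hard gain is `sqrt(max(x, 0))`; the smoothed variant
replaces `[0, eps]` by the concave quadratic that joins `sqrt` with
matching value and slope, is zero at and below threshold, converges
pointwise to the hard gain as `eps -> 0`, and keeps one-sided slopes
finite for Jacobians.  Tiny RK4 overshoots of the invariant set
(`u, a >= 0`, `s <= 1`) are clipped.  Non-finite states abort with a
diagnostic.

## Spiking counterpart

Two pools of adaptive leaky integrate-and-fire neurons (20 per pool by
default — small pools are intentional: finite-size noise is part of
what the spiking comparison probes — 200 pF, 10 nS leak, -70/-50/-60 mV
rest/threshold/reset, 2 ms refractory).  Each spike increments a
calcium-like variable (decay 2 s) gating an outward current toward the
K+ reversal — the local-fatigue analogue — and can depress the
neuron's outgoing synaptic resources (release fraction, default 0,
recovery 2 s).  Cross-pool inhibition is conductance-based (reversal
-75 mV, 8 ms decay), normalized by pool size.  The protocol maps to
current as `300 pA * S(t)` on top of a 210 pA constant background —
just above the 200 pA rheobase, so pools fire at a few hertz without
drive — plus white current noise (30 pA).  Euler steps of 0.1 ms; all
randomness (initial jitter, noise) comes from one seed.

At this operating point the spiking circuit reproduces, per seed, the
off-state memory (the dominant pool alone keeps a nonzero off-state
rate) and dynamic L4 (longer dominance at longer frame intervals in
10/10 tested seeds), and, on average across seeds, habituation — the
first rested epoch outlasts the steady state clearly, and the second
epoch slightly.  Per-seed first-versus-second epoch ordering is not
reliable at 20 neurons per pool: finite-size noise is strong, and the
habituation window of the spiking model is narrower than the rate
model's.  Tests therefore assert seed-averaged habituation and
majority-of-seeds dynamic L4.  Run-to-run variability of the mean
dominance duration decreases from 20 to 60 neurons per pool; the mean
itself also shifts with pool size (noise-driven release becomes rarer),
so variability comparisons hold at matched parameters only.

## Survival stage

Dominance durations are survival times in movie frames; block ends
right-censor the running percept.  Records are built from report
times: consecutive report intervals (including block start to first
report) are uncensored durations, the tail interval is censored, and
durations are rounded to whole frames (minimum one).  Screening keeps
blocks with at least two reported switches and drops subjects with no
valid block.  The hazard-ratio fit is a Cox proportional-hazards model
with one fixed covariate (frame interval in ms, or epoch) and a
subject-level random effect, delegated to R `survival::coxph` with a
gaussian frailty term via an `Rscript` subprocess; a lifelines
fallback fits the marginal model with cluster-robust errors (and no
frailty variance).  The proportionality diagnostic follows the
two-step offset procedure: the per-subject random effects form the
noise vector `z = y_hat - theta*x`, a plain Cox model is refit with
`z` as offset, and the scaled Schoenfeld-residual slope over time is
tested (`cox.zph`); p > 0.05 passes.

The synthetic report generator emulates the quartet study design (16
subjects; test blocks of 300/350/400/450 ms frame periods lasting
5/5/6/8 minutes): per-subject gamma frailty (mean 1, variance 0.05 by
default), exponential dominance durations with log-hazard linear in
the centred frame interval and in epoch at the study's reported effect
sizes (hazard ratios 0.996 per ms and 1.024 per epoch), with the epoch
effect saturating after 30 epochs so habituation reaches a steady
state instead of compounding without bound.  The default baseline of
62 frames makes a full synthetic study yield on the order of 1.3k
records, the scale of the human dataset.  What the generator does not
emulate: reaction-time lag between neural switch and key press,
percept-type composition (rotation versus orientation percepts are not
distinguished), non-exponential duration shapes (human dominance
durations are typically gamma-like), and learning across blocks.
Passing recovery and calibration tests therefore show the *pipeline*
is correct and calibrated, not that these simplifications hold in real
data.  Two statistical caveats found during calibration and reflected
in the tests: cluster-robust Wald p-values are only uniform under the
null with enough subjects (tests use 24; with ~6 clusters the sandwich
variance is unreliable), and fitting one covariate at a time on data
generated with both effects attenuates both estimates (the recovery
checks therefore generate one effect at a time).

## Known limitations

* Profiles are calibrated to qualitative *regimes*, not to specific
  experimental curves.
* The no-alternation boundary is sensitive to the pulse width
  convention (see above).
* The smoothed gain keeps a corner at zero (finite slope change); a
  fully smooth variant would need positive output below threshold,
  which the contract excludes.
* The nonlocal-fatigue member shows escape-driven intermittent rivalry
  whose dominance durations are nearly flat in the frame interval;
  dynamic L4 is carried by the local-fatigue member.
* The spiking model is an adaptive-LIF idealization, not a
  Hodgkin-Huxley reconstruction; only qualitative regime parity is
  claimed.
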