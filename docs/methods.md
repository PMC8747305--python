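# Methods

This note documents the models implemented in `trunkmoment`, the synthetic
data they are exercised on, and the numerical and design choices a user
should know before trusting or modifying the results.

## Coordinate and sign conventions

Sagittal plane only: x forward, y up. Segment orientations are measured
from the global vertical, forward lean positive; joint flexion angles are
positive. Moments about L5/S1 are in newton-metres with **extension
positive**, so gravity acting on a flexed trunk produces a positive
(extensor) demand. All trial channels live on a uniform 50 Hz time base.

## Planar body model

The body is a five-segment chain — lumped feet, shanks, thighs, pelvis,
trunk+head, plus a lumped arm segment hanging from the shoulder. Segment
masses, lengths, centre-of-mass fractions and radii of gyration are fixed
fractions of body mass and stature (documented constants in
`anthropometry.py`, in the style of classical cadaver-based tables), scaled
per subject. The L5/S1 joint is placed at the distal end of the pelvis
segment, 0.090 × stature above the hip-joint midpoint — a documented
convention, since the anatomical location cannot be derived from the data
this package handles. All study tasks are sagittally symmetric, which is
why a planar chain suffices for every quantity the downstream models
consume.

## Inverse dynamics

`bottom_up_moment` balances the foot–shank–thigh–pelvis subsystem about the
instantaneous L5/S1 position:

    M_net = (x_cop − x_p)·F_y + y_p·F_x
            − Σ_low [ m_i((x_i − x_p)(a_{y,i} + g) − (y_i − y_p) a_{x,i}) + I_i·φ̈_i ]

Positions, forces and centre of pressure are low-pass filtered (2nd-order
Butterworth, 5 Hz, zero-phase) before double central differentiation; this
is what keeps the recursion usable on noisy measured data, at the cost of
attenuating genuine content above a few hertz. In exoskeleton trials the
human share is `M_Human = M_Net − M_Exo` with the support torque taken from
the trial's torque channel.

## EMG-driven muscle model

Twelve elements with fixed anatomy (moment arm 0.045–0.080 m, PCSA
7–18 cm², normalized strain per radian of lumbar flexion = moment arm /
nominal fibre length; table in `emgmod.py`, fully overridable). Lumbar
flexion (thorax relative to pelvis) drives normalized length; extensors
lengthen in flexion, flexors shorten. Hill-type factors:

* active force–length: Gaussian `exp(−((λ−1)/w)²)` — 1 at optimum;
* force–velocity: piecewise linear, `1 + S_e·min(λ̇/λ̇_ref, 1)` when
  lengthening and `max(0, 1 − S_c·min(−λ̇/λ̇_ref, 1))` when shortening,
  with fixed reference rate λ̇_ref = 1 s⁻¹;
* passive (dorsal elements only): exponential stress
  `S_p(e^{c(λ−λ₀)} − 1)` beyond the slack length λ₀, fixed shape `c = 8`.

The seven calibrated parameters, bounds in parentheses: EMG-to-stress gain
`G` (10–120 N/cm² per unit activation), passive slack position `λ₀`
(0.9–1.3), passive scale `S_p` (0–60 N/cm²), eccentric and concentric
force–velocity scales `S_e` (0–0.8) and `S_c` (0–1), optimum lumbar angle
`θ_opt` (0–1.2 rad) and the active force–length width `w` (0.2–1.0). Only
six contractile properties are standard in this model family; the seventh
slot is implemented as the force–length width, which is the natural free
shape parameter once the others are fixed — this choice is flagged as a
design decision, as is driving muscle length from lumbar flexion rather
than whole-trunk inclination.

### Calibration

The objective is the rectangle-rule discretization of the integrated
squared moment residual (Δt = 0.02 s), pooled over the calibration trials
with equal weight. It is minimized as a bound-constrained nonlinear
least-squares problem (scipy's trust-region reflective solver) on the unit
cube, which makes trust-region scaling and finite-difference steps
comparable across parameters of very different magnitudes. A quasi-Newton
box solver proved unreliable here: the objective has strong local minima
(e.g. `θ_opt` pushed to its bound with an inflated gain), in which L-BFGS-B
regularly terminated. Starts are the box midpoint plus a seeded
Latin-hypercube sample (default 5); the best final objective wins, ties
broken by the lower gain. Multi-starts matter most for small calibration
sets — single-trial objectives are the most degenerate. An optional sample
stride subsamples the 50 Hz calibration data (scaling Δt to match); strides
of 2–4 move the optimum negligibly because neighbouring samples are almost
perfectly correlated.

## Reduced-sensor regression

Features (9): the four longissimus EMG channels (pars lumborum and pars
thoracis, both sides) plus trunk inclination, its angular velocity and
acceleration, trunk flexion (thorax vs thigh) and hip angle (pelvis vs
thigh) — the kinematics an exoskeleton measures itself. The learner is an
ε-SVR with Gaussian kernel in the documented "coarse" convention: features
are z-scored (training-set constants, frozen at prediction time; whether
the original pipeline standardized is unstated, so this is a recorded
choice), kernel scale `4·√9 = 12`, box constraint `IQR(response)/1.349`,
tube width `IQR(response)/13.49`. The response is always EMGMod's active
moment — never the ID moment — exactly as the pipeline prescribes, so
RegMod inherits EMGMod's errors by construction. Ten-fold cross-validation
is reported as a diagnostic with folds blocked by trial (contiguous
blocks), because rows within a trial are serially correlated and random
row-level folds would leak. Note the ε tube bounds attainable accuracy:
residuals inside the tube are free, so CV RMSE plateaus near
`IQR/13.49 ≈ 6–8%` of the response SD even on noise-free learnable
targets. Training rows can be capped by uniform decimation (default 2000)
to bound the cubic solver cost; at 50 Hz this discards almost no
information.

## Synthetic data generator

The generator is the study's stand-in for the unavailable human cohort.
Joint angles follow piecewise minimum-jerk profiles; every derivative is
analytic, so the ground reaction force and centre of pressure computed from
whole-body Newton–Euler balance are *exactly* consistent with the
kinematics, and the analytic top-down moment about L5/S1 is an independent
oracle for the bottom-up implementation (they share only the anthropometry,
not the code path or the differentiation scheme).

Study conditions (defaults):

* 14 calibration conditions (2 masses × {stoop, squat} × {slow, normal} +
  2 masses × free × {very slow, normal, fast}), two repetitions each; test
  battery: 16 exoskeleton lifts (2 masses × {normal, fast} × 4 control
  strategies), stacking lift + carry, 2 shelf lifts, push and pull.
* Movement time per phase (lower, then lift): 6 / 4 / 2.5 / 1.5 s for very
  slow / slow / normal / fast. The published protocol gives no timings;
  these are invented, configurable defaults, and the per-phase reading also
  keeps the lift spectra inside the 5 Hz measurement band (see below).
  0.6 s of quiet standing pads each end; the box is gripped during a 0.5 s
  dwell at the deepest posture, modelled as a smooth hand-force ramp (grip
  force builds gradually — and a force step would be smeared by the ID
  filters while remaining sharp in the oracle).
* Posture targets: stoop ≈ 8° knee / 90° trunk flexion; squat ≈ 110° knee
  with trunk inclination ≤ 30°; free in between. Carry is an upright hold
  with 0.1 rad sinusoidal sway at 0.8 Hz (planar stand-in for walking —
  gait dynamics are out of scope and flagged as such); shelf lifts raise
  the load to 1.5 m by arm elevation; push/pull is isometric with ±98.1 N
  horizontal hand force (a 10 kg tensioning mass).
* Exoskeleton strategies: τ = k₁α (inclination), k₁α + k₂α̈ (dynamic),
  k₁α + k₃α̇ (velocity), 0 (transparent), with k₁ = 30 N·m/rad,
  k₂ = 1 N·m·s²/rad, k₃ = 5 N·m·s/rad. The EMG-hybrid strategy is out of
  scope (it needs forearm EMG).

EMG is synthesized by inverting the ground-truth muscle model: the passive
moment at the true parameters is subtracted from the human moment, the
agonist elements receive one shared activation solving the active-moment
equation exactly (fixed equal-drive synergy — chosen so the calibration
problem has a recoverable optimum), antagonists sit at a co-contraction
baseline (default 3% MVC) that is compensated within the solve, and roles
swap when the demanded moment is flexor. Noise: per-channel multiplicative
log-normal EMG noise (mean-one, SD 0.05) and additive white angle noise
(SD 0.005 rad) on the wearable-grade angle channels, whose rates are then
re-derived by 5 Hz filtering and differentiation. Laboratory-grade signals
(marker positions, forces) are left noise-free: ID is the study's reference
and is treated as reference-grade. Activations are clipped at 1.5 × MVC; a
trial whose pre-noise demand exceeds the cap is flagged in its metadata.
Ground-truth physiology is drawn per subject from ranges well inside the
calibration bounds (e.g. gain 30–55 N/cm², θ_opt 0.40–0.70 rad), body mass
and stature from a young-male cohort (73.8 ± 7.6 kg, 1.82 ± 0.09 m). Every
trial is seeded deterministically from (study seed, subject index, trial
id).

What passing tests therefore show — and don't: the pipeline implementation
is internally correct (dynamics consistent to < 0.5 N·m RMS, conservation
to 1e-6 N·m, parameters recoverable, calibration-set orderings reproduced
directionally). They do not show that the muscle model is an adequate
description of real trunk physiology: the generator's EMG obeys the model
family by construction, has a fixed synergy, no electromechanical delay, no
fatigue, no marker soft-tissue artefact, and its noise is far tamer than
surface EMG. Absolute RMSEs here (a few N·m) are accordingly much smaller
than on real subjects (~20 N·m); only orderings and ratios carry over.

## The calibration-set study

Calibration sets are defined over the 14 *conditions*; both repetitions of
a member condition are always included. The Selected-family criterion
requires both masses, both distinct techniques (stoop and squat), and both
velocity extremes, where any very-slow/slow trial covers the slow extreme
and the fastest class present (fast) must appear; since fast exists only
for free lifts, every member is {stoop, squat, free-fast} with mass and
speed coverage — 18 sets, verified against a brute-force filter of all 364
3-subsets. The Worst-selected member maximizes the across-subject mean
RegMod RMSE over all test trials (ties broken lexicographically). The
default study evaluates Full, the Selected family and Quasi-static; the
exhaustive n ∈ {1, 2, 3} subset sweep (469 evaluations per subject) is
gated behind a flag and runs with cheaper numerical settings (single
start, looser tolerance, sample strides) — appropriate because only the
across-subset ordering is consumed. Per-task-group RMSE pools squared
errors over all samples of the group before taking the root. The two-way
within-subject ANOVA is computed directly from the sums-of-squares
decomposition with subjects as the blocking factor, each effect tested
against its subject interaction, no sphericity correction (none is reported
in this literature); post-hoc paired t-tests are Bonferroni-adjusted as
`min(1, m·p)`. The implementation is cross-checked against an independent
library implementation in the tests.

## Problem sizes

Default scales used by the shipped study and acceptance script: 10
synthetic subjects for the evaluation study, 20 for parameter-recovery
statistics in the test suite (12 in the acceptance script), and the subset
sweep on a reduced subject count (4) in the acceptance script. These sizes
give stable orderings on this generator; all are configuration values.

## Known limitations

* Planar, symmetric tasks only; no frontal/transverse moments, no gait.
* One shared activation per muscle role in the generator — real
  inter-muscle variation enters only through noise.
* The passive parameters (λ₀, S_p) are jointly unidentifiable when the
  motion never stretches tissue beyond slack; only the passive *moment* is
  then determined.
* Whether the original pipeline's filters were zero-phase is unstated;
  zero-phase is the default here (offline practice; preserves
  synchronization), with a causal flag for online-style use.
* Trial files are plain text and readable, not compact; a 14-condition
  session is a few megabytes.
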