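# Methods

## The model

`submovekit` treats a 3D target-directed arm reach as the sum of a small
number of overlapping, stereotyped **submovements**, each hypothesized to
implement one discrete correction of the ongoing movement. Each
submovement is a minimum-jerk pulse with five parameters — initiation
time `t0` (s), duration `D` (s) and amplitude vector `A = (Ax, Ay, Az)`
(cm) — whose per-dimension velocity is

    v_d(t) = (A_d / D) · 30 τ²(1−τ)²,   τ = (t − t0)/D ∈ [0, 1],

zero outside the support. This is the classic minimum-jerk speed profile;
its integral over the support is exactly `A_d`, so displacement is
conserved by construction. The minimum duration is fixed at 0.1 s, the
approximate timescale of a muscle-twitch force transient. All positions
are in cm, times in seconds, sampling at 100 Hz.

The package implements four stages:

1. **Preprocessing** (`io`): resampling to a uniform 100 Hz grid,
   cubic-spline interpolation of occlusions of at most 5 samples (50 ms),
   exclusion of trials with longer occlusions, zero-phase 4th-order
   Butterworth low-pass filtering at 10 Hz, and central-difference
   velocity/acceleration.
2. **Decomposition** (`decompose`): for each candidate count N, bounded
   nonlinear least squares over the 5N parameters minimizes

       J = Σ_d ∫ (v_rec,d − v_meas,d)² dt
           + λ Σ_d ∫ (Σ_j |v_j,d| − |Σ_j v_j,d|) dt ,

   where the second term penalizes simultaneous submovements of opposite
   sign in the same dimension (without it, pairs of large opposing pulses
   can cancel and inflate N). The optimal N is the knee of J(N): after
   min-max normalizing both axes, the point furthest below the descending
   diagonal from (0, 1) to (1, 0), ties toward smaller N.
3. **Prediction** (`features`, `nets`): three small feed-forward networks
   predict, from causal kinematic features only, (a) whether a corrective
   submovement has begun at the current timestep, (b) the new
   submovement's 3D amplitude, (c) its duration.
4. **Closed loop** (`closed_loop`): the three networks drive a simulator
   whose inputs come from its own generated trajectory, so errors
   propagate as in real reaching. Success is 1 s of continuous dwell
   inside the 1.27 cm target sphere; failure is 3 s of simulated time or
   30 triggered submovements.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `d_min` | 0.1 | s | minimum submovement duration (twitch timescale) |
| `d_max` | 2.0 | s | upper duration bound, also the duration decode scale |
| `lambda_overlap` | 0.01 | — | opposing-overlap penalty weight, relative to the trial's RMS speed so both cost terms carry (cm/s)² units |
| `n_range` | 1..10 | — | candidate submovement counts |
| `n_restarts` | 5 | — | multi-start count per N (2–3 used in the corpus studies) |
| filter cutoff | 10 | Hz | zero-phase Butterworth low-pass |
| `gap_max` | 5 | samples | longest interpolable occlusion (50 ms) |
| target radius | 1.27 | cm | virtual spherical target |
| dwell / timeout / cap | 1.0 s / 3.0 s / 30 | — | closed-loop stopping rules |
| hidden units | 5 / 10 / 10 | — | initiation / amplitude / duration networks |

## Decomposition numerics

The fit runs on the residual form of J with an analytic Jacobian; the
penalty residual `sqrt(λ dt (Σ|v_j| − |Σ v_j|))` is non-smooth where a
component changes sign, which trust-region reflective least squares
tolerates (the subgradient is used there). Initialization is matching
pursuit: the best single pulse is fitted to the residual velocity (a
coarse search over durations with the linear-optimal amplitude per
candidate), subtracted, and the process repeated N times; restarts
jitter the seed, with an additive amplitude component so a
zero-amplitude pulse — a saddle with no gradient toward unfitted
submovements — can escape. The N+1 fit is warm-started from the N fit
plus one pulse fitted to its residual, and a zero-amplitude extra
submovement reproduces the N-cost exactly, so the cost curve is
non-increasing in N by construction. A degenerate (constant) cost curve
selects the smallest N with a warning; knee ties break toward smaller N
within float tolerance.

## Features and targets

At any instant the causal state is: start, target, the submovements
already initiated, and the fingertip kinematics. The three feature
vectors (21 / 24 / 12 values, orders frozen in `features.py`) are built
from pairwise distances or 3D differences among derived positions
("current submovement start/end" are planned-trajectory positions at the
current submovement's `t0` and `t0 + D`), plus timing features
(`e^(−20t)` emphasizes the early part of each submovement) and the
sign-preserving 4th root of velocity and acceleration, which compresses
their heavy-tailed distributions.

Amplitude features and targets are divided by **DTTAPS**, the distance
from the endpoint implied by all prior submovements to the target
(start-target distance for the first submovement; floored at 0.1 cm), so
large and small corrections train on a common scale. Normalized
amplitudes are signed, so they are mapped affinely from [−r, r] to
(0, 1) for the logistic outputs, with r the largest magnitude seen in the
training fold (stored with the model). Durations are scaled by 2.0 s and
clamped to ≥ 0.1 s on decode.

Initiation training rows are generated per decomposed submovement window:
for submovement k, one row per 10 ms step from its onset to at least
0.1 s past the next onset (so every correction contributes a full step of
positive labels even when it launches after its predecessor ends),
labeled 1 at and after the next onset ("step" labels; an "impulse"
variant labels only the onset step). The last submovement's window runs
through the recorded dwell tail, putting the quiet at-target state into
the training distribution — the state the closed loop occupies while
dwelling. Decoding takes the first output strictly above 0.5, matching
how the closed loop consumes the network. Step labels were chosen over
impulses because the decode only needs the first crossing and impulses
leave one positive row per ~50, too imbalanced for stable thresholding.

Two input-conditioning choices matter in closed loop. First, the
DTTAPS-normalized position differences pass through a signed `log1p`
before z-scoring: when the remaining distance is a few centimeters,
ratios like |target − start| / DTTAPS reach 20–50 and would saturate the
tanh layer, drowning the unit-scale direction components that carry the
signal. Second, first-submovement amplitude/duration rows use the
at-rest state (position = start, zero velocity and acceleration) rather
than the measured kinematics at t0: the zero-phase filter is
anti-causal, so measured kinematics at movement onset already contain a
smear of the upcoming pulse that no causal predictor could see — a
network keying on it mispredicts badly when the simulator's state really
is at rest.

## Training

Each network is one tanh hidden layer with logistic outputs, trained by
full-batch Adam (lr 0.02, ≤ 2000 epochs) on mean squared error with
early stopping on validation loss (patience 200 epochs — full-batch
training improves slowly and a short patience stops far too early).
Initiation rows are weighted so positive and negative labels carry equal
mass: with step labels positives are roughly one row in seven, and an
unweighted fit estimates the class-conditional probability, which rarely
crosses the fixed 0.5 decode threshold.
Inputs are z-scored with statistics from the training folds only.
Cross-validation is 10-fold with reaches (never rows) assigned 80:10:10
to train:validation:test, so no reach leaks into the model that scores
it. The networks are implemented directly on numpy: logistic output
units and reach-wise validation splits for early stopping are not
expressible in the stock scikit-learn MLP.

Initiation evaluation is per submovement window: a window with a true
next onset and a 0.5-crossing is a true positive (onset-time VAF and RMSE
are computed over these, relative to the window start); a crossing with
no true onset is a false positive; the converse a false negative; neither
is a true negative. The general event-matching API in `metrics` instead
pairs predicted and true onset times greedily within a 0.10 s tolerance
(one minimum submovement duration) — that tolerance is a package choice,
made configurable because any event-level confusion accounting
presupposes some correspondence rule.

## The synthetic generator

`synthetic` emulates the statistical structure the pipeline assumes:
radial reaches of 20–70 cm (mean ≈ 45 cm) whose first submovement covers
a uniform 0.6–0.9 fraction of the start-target distance (deliberate
undershoot, the canonical strategy that avoids energy-expensive
direction-reversing overshoots). Two correction policies are available:

* **aimed** (default): every subsequent correction aims at the target
  and misses by a uniform 0.1–0.25 fraction of the remaining distance,
  the reach closing exactly once the error is below 1 cm; the
  submovement count (2–5) emerges from the geometry. This is the
  stochastic-correction account of reaching — error proportional to
  movement extent, corrected iteratively — and it makes the amplitude
  mapping conditionally deterministic: at any state the expected
  amplitude is the remaining vector, a property that survives even when
  decomposition merges adjacent corrections (merged aimed corrections
  still sum to "aim at target") and that makes the closed loop
  self-correcting.
* **fractional** (`GeneratorConfig.well_separated()`): corrections
  deliberately cover a 0.4–0.6 fraction of the remaining vector, with a
  fixed drawn count of 2–4. With f ≈ 0.5 successive submovements carry
  comparable velocity power, so every true submovement is resolvable by
  the knee criterion — the regime for parameter-recovery studies. With
  aggressive or aimed corrections, trailing submovements are
  centimeter-scale and fall below the knee's resolution (roughly one
  normalized axis step of cost share), a limit of knee-based model-order
  selection, not of the optimizer.

Durations follow `D = 0.2 + 0.01·|A| + N(0, 0.04)` s (a 34 cm primary
submovement lasts ~0.54 s, matching rapid human reaches), and each
correction is initiated at a uniform 0.8–1.3 phase of the ongoing
submovement's duration — timing is tied to the movement state because
the generator's policy is exactly the mapping the networks are asked to
recover; a policy with state-independent random gaps would be
unlearnable by construction. Phases above 1 are corrections launched
after a short pause, which teach the initiation network to distinguish
"submovement ended, still off target → correct" from "ended on target →
quiet". Velocity noise is band-limited white noise (RMS 0.5 cm/s,
low-passed at 6 Hz) integrated into the positions, chosen below the
10 Hz preprocessing cutoff so that tests exercise nonzero residuals.
Occasional 1–3-sample gaps emulate marker occlusion.

What the generator does **not** emulate: signal-dependent neuromotor
noise, biomechanical (joint, muscle) constraints, movement-speed/accuracy
trade-offs beyond the duration rule, or any dependence of the correction
policy on sensory delay. Passing tests therefore show that the pipeline
recovers a known submovement-generating policy from kinematics — not
that human reaching obeys that policy.

## Problem sizes

The parameter-recovery study uses 50 well-separated reaches decomposed
over counts 1..10 with 3 restarts; the prediction/closed-loop study uses
400 default-policy reaches over counts 1..7 with 2 restarts, which gives
the amplitude and duration networks on the order of a thousand training
rows (they have ~280 parameters; smaller corpora leave them visibly
data-limited). Both run in minutes on one CPU. Examples use 12–20
reaches.

## Known limitations

- The knee criterion under-counts submovements whose amplitude share of
  the velocity power is below roughly one normalized axis step (~1/9 for
  counts 1..10); such reaches resolve within ±1. On the aimed-policy
  corpus this merges trailing corrections, which puts the summed
  decomposed amplitudes of a reach ~2 cm from the target (the generating
  policy: 0.2 cm) — the main source of terminal error in the closed
  loop, since the networks can only learn the decomposed description.
- Initiation-time VAF on synthetic data reflects how much of the
  generator's timing is state-determined; the residual uniform phase
  jitter is irreducible for a deterministic predictor.
- The closed loop is deterministic: repeated simulations to one target
  produce one trajectory, with none of the trial-to-trial variability of
  real reaching. Its failures are stalls just outside the 1.27 cm target
  radius with no recovery trigger: the knee-merged training corpus
  contains no examples of corrections launched from a quiet, nearly
  on-target state.
- Decomposition assumes the reach is fully covered by the trial window;
  submovements truncated by the recording end bias the fitted durations.
- In the amplitude tables the cm-domain VAF of first submovements is
  dominated by cross-reach spread in target distance and direction;
  prediction-quality trends across submovement indices are better read
  from the per-index RMSE, which falls monotonically.
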