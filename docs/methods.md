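# Methods

## Motion representation and pre-processing

Motion is represented as per-frame unit quaternions `(w, x, y, z)` for a
17-joint upper-body skeleton, of which 10 joints feed the networks (left
and right hand, forearm, upper arm, shoulder; head; sternum).  The full
skeleton enumeration (seven midline joints plus bilateral clavicle,
shoulder, upper arm, forearm, hand) is this package's configuration choice;
the tracked-site list it mimics does not pin the exact segment set, so the
joint sets are configurable throughout.

All quaternions are **canonicalized**: normalized to unit length and
sign-fixed so `w ≥ 0`.  Since `Q` and `−Q` encode the same rotation, this
gives each rotation a unique representative and keeps network inputs in one
half-space.  The **geodesic distance** between rotations is
`d(q, q') = |log(q' q⁻¹)|` on the canonical branch — half the relative
rotation angle, in `[0, π/2]`.  **SLERP** implements
`q(w) = q₁ exp(w log(q₁⁻¹ q₂))` with a shortest-arc sign flip when
`dot(q₁, q₂) < 0`; equal steps in `w` give equal geodesic steps.
**Mirroring** swaps left/right joints and maps `(w, x, y, z) → (w, x, −y, −z)`
(re-canonicalized); it is an involution and preserves geodesic distances.

The canonical internal frame rate is 90 fps (the real-time loop rate);
lower-rate captures are resampled on load by per-joint SLERP between
adjacent frames (hand tracks linearly).  Hand positions are obtained by
forward kinematics over a three-segment chain (shoulder offset 0.20, upper
arm 0.30, forearm 0.30 scene units from a configurable root); these are
plausible avatar dimensions, not measured ones, and only relative motion
matters downstream.

## Synthetic dyads

The generator emulates the study conditions rather than any individual's
style.  Each leader joint rotates about a fixed random axis with an angle
that is a seeded sum of 2–3 sinusoids, frequencies 0.2–1.0 Hz and total
amplitude 0.15–0.6 rad for the active (left) arm, 15% of that for the other
joints.  The band was chosen to match slow mirror-game arm sweeps and so
that the *speed* profile — whose norm rectifies the velocity and creates
harmonics — keeps under 1% of its power above the 4 Hz analysis cutoff.

Followers are delayed copies: `follower(t) = leader(t − lag)` (default lag
20 frames ≈ 222 ms, a plausible human reaction delay), with each joint
perturbed by a random rotation of geodesic magnitude `|N(0, σ)|`
(default σ = 0.02 rad).  Improvisation trials alternate ground-truth roles
in 10 s blocks; each player's trace spherically crossfades over 0.5 s
between "own motion" and "delayed copy of the partner" at block switches,
because hard switches create position discontinuities whose filtered-speed
spikes corrupt windowed lag estimation.  Per-trial seeds derive from the
master seed via a SplitMix64-style integer hash, so corpora are
bit-reproducible across platforms.

Balanced Turing decision tables (half artificial, half human, shuffled) are
generated with oracle / inverted / uniform-random / biased guess policies.

What the generator does **not** emulate: intentional communication
(gestures, waving), motor variability that adapts over a session, tremor,
and tracking artifacts.  Passing tests therefore demonstrate correctness of
the algorithms and recoverability of known ground truth, not performance on
recorded human motion.

## Networks

Both networks are LSTMs with dense readouts, implemented in numpy with
full backpropagation-through-time (gradient-checked against numerical
differentiation), RMSprop (decay 0.9), MSE loss on canonical quaternion
components, and optional global-norm gradient clipping at 5.  Training is
deterministic given the seed.

**Follow-net.**  Input: the partner's last `history = 120` frames at
`stride = 4` → 30 frames × 40 features; output: the agent's own 40-vector
at the next full-rate frame.  Window `t` uses input frames
`t − history + stride, …, t` and target frame `t + 1`, giving
`T − history − 1` windows per trial.  Defaults: one LSTM layer of 128
units, dense 128 → 64 → 40 (linear output), 15 epochs, learning rate 1e-3.
Raw outputs are renormalized per joint to canonical unit quaternions only
at inference.  The rollout is causal by construction (predictions never
feed back); the first `history + 1` output frames hold a rest pose (the
mirrored first leader frame — a neutral choice).

**Lead-net.**  Sequence-to-sequence next-chunk prediction at the stride-4
subsampled rate (22.5 Hz): a per-time-step readout over the LSTM's hidden
states predicts the frame one chunk-length ahead, so feeding a chunk
returns the next chunk.  The chunk length (10 s) follows from 150 s of
generation over 15 recursive feedbacks.  Gaussian input noise
(σ = 0.01 in component space) regularizes training only.  Generation
renormalizes every pass, SLERP-upsamples to 90 fps, and keeps the first
120 s.  Two alternative decoders were evaluated and rejected: per-step
autoregressive feedback freezes (the next-frame mapping at 22.5 Hz is close
to identity, so free-running collapses to a fixed pose), and coarser model
rates did not cure it.  The flat next-chunk form regresses toward the
conditional mean over recursions, so generated motion is smaller and
smoother than the training corpus — a desk-scale amplification of the
open-loop limitation inherent to replaying pre-synthesized motion.
Independently predicted chunks meet with a small pose jump; a 1 s spherical
crossfade at each seam removes the resulting speed spikes.  Because the
generated motion is near-static after the first chunk, relative spectral
measures on its speed profile run on a small denominator; the
below-4 Hz-dominance property holds for the tested configuration but with a
thin margin.

## Agent controller

The agent's pose is a per-joint SLERP between follow-net output and the
pre-generated lead sequence with lead-weight `w`: 0.1 following, 0.9
leading, ramping linearly over 1 s at role changes (instant jumps would
defeat the purpose of spherical blending).  During improvisation the role
coefficient is redrawn every 4 s with the current switch probability
(start 0.5); while following dominated the trailing 20 s window
("dominated" = follow fraction above 50%, a definition this package fixes)
the probability of becoming leader grows by 0.01 per decision and resets to
0.5 upon becoming leader.  A hand distance above 0.3 scene units forces the
coefficient to 0 on that frame; the 4 s clock is not reset by the trigger.
The distance is evaluated per frame between the 4 Hz-filtered partner hand
track and the agent's previous-frame forward-kinematics hand position
(strictly causal).  All stochastic decisions come from one injected seeded
generator and are logged per frame (coefficient, weight, switch
probability, trigger flag, distance).

With symmetric unbiased switching the role process is a two-state Markov
chain with stationary distribution ½/½; the balancing bias keeps long-run
leading fractions within a few points of 50%.

## Kinematics and coordination

Hand tracks are low-passed at 4 Hz (order-4 Butterworth, forward–backward,
zero phase; only the cutoff is prescribed, the realization is this
package's choice).  Velocity is the per-frame displacement vector; its
printed definition is a difference with reversed sign and no `Δt` division,
which leaves the speed norms unchanged, so speeds are reported in scene
units per frame (an optional fps factor converts to units/s).  Trial means
divide by the number of defined samples (`T − 1` speeds, `T − 2`
accelerations).  The inter-hand distance `d(t)` uses the `(x, y)`
components exactly as printed, with a 3-D variant off by default.

WTLCC correlates each 300-frame window of the focal speed profile with the
partner's profile shifted by every integer lag within ±90 frames, stepping
50 frames; the correlation is Pearson's r, ties break toward the smallest
absolute lag and then toward the negative one, and windows with zero
variance (either segment) are skipped and excluded from `W`.  **Positive
lag means the focal player trails (follows).**  This sign convention
reproduces the documented extremes: `r_LF → 100%` when instructed to
follow, `→ 0%` when leading.  Exact antisymmetry under swapping the players
holds for pure delayed copies; for general signals the focal player anchors
the window grid, so the swapped analysis evaluates windows shifted by the
lag and the per-window lags agree only approximately.  Improvisation trials
with exactly balanced role blocks recover mean `r_LF` near 50%, with
per-trial scatter of several points from windows that straddle block
boundaries.

## Evaluation

Confusion metrics use `ε = |s − s̃|` with `s = 1` for artificial partners:
FNR is the mean error over true-artificial trials, FPR over true-human
trials, reported in percent, stratifiable by condition or trial-duration
class; a stratum with no trials of a class reports NaN, never 0.

The sensitivity analysis freezes one leader joint to a replacement
orientation across the whole input window (a constant pose sampled from
other frames of the corpus) and measures the mean geodesic displacement of
each output joint, averaged over `n_sequences = 100` windows and
`n_replacements = 10` draws by default (both are configuration; the
protocol's exact averaging counts are not prescribed).  On a model trained
on identity-coupled dyads every row of the resulting matrix peaks at the
anatomically corresponding follower joint, and a leader joint that carries
no usable signal yields a near-zero row.

## Numerical and testing choices

Quaternion logs use the canonical branch (sign fixed before the log);
near-identity rotations use a sinc-safe series guard.  The independent
oracle for rotation algebra in the tests is `scipy.spatial.transform`
(never used by the implementation itself); WTLCC is checked against a naive
exhaustive double loop; confusion rates against plain counting.  Tests run
the full training path at reduced size — 40-frame history, 64 hidden units,
30 s trials, 2 s lead-net chunks — sizes chosen so the whole suite trains
three networks in well under a minute on one CPU while leaving the
package's defaults at the full study values (history 120, stride 4, 15
epochs, learning rate 1e-3, 90 fps, window 300/50/±90).

## Known limitations

* The lead-net generates open-loop: it cannot react to the partner beyond
  the superimposed 10% follow component, and its recursive output is
  damped relative to the training corpus.
* The synthetic world is stationary and noise-free by default; none of the
  drift, occlusion or soft-tissue artifacts of real motion tracking are
  modeled.
* Forward kinematics uses nominal segment lengths; absolute hand distances
  (and hence the 0.3-unit trigger) are only as meaningful as those lengths.
* `r_LF` quantizes to the window count (one window flips the ratio by
  `100/W` points), so short trials give coarse role estimates.
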