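# mirrorgame

A dual recurrent-network controller for human-like motion in the 3-D
mirror game, together with the analysis toolkit used to evaluate such an
agent against human behavior: kinematic summaries, windowed time-lag
cross-correlation (WTLCC) leader/follower statistics, Turing-test confusion
metrics, and perturbation-based joint-sensitivity analysis.

## Who this is for

Researchers in computational cognitive science and human–robot interaction
studying dyadic motor coordination: how two agents negotiate leading and
following, how tightly a reactive controller can mirror a partner, and
whether sensorimotor coupling alone makes an artificial partner feel human.
Everything runs on synthetic, fully seeded dyads, so the entire pipeline is
testable without motion-capture recordings.

## The model

Upper-body motion is a sequence of unit quaternions `q = (w, x, y, z)` for
10 joints (both arms: hand, forearm, upper arm, shoulder; head; sternum) at
90 fps.  Quaternions are canonicalized (unit norm, `w ≥ 0`), and all
right-arm-active data is mirrored to the left (`(w, x, y, z) → (w, x, −y, −z)`
with left/right joints swapped) so one network serves both sides.

Two LSTM networks control the agent:

* **follow-net** — reactive: predicts the agent's next-frame joint
  orientations from the partner's last 120 frames sampled at every fourth
  frame (30 × 40 features ≈ 1.3 s).  Trained with RMSprop, learning rate
  1e-3, MSE on quaternion components, 15 epochs.
* **lead-net** — generative: a sequence-to-sequence chunk predictor whose
  output is recursively fed back 15 times to synthesize 150 s of open-loop
  motion (the first 120 s are used), with Gaussian input noise as training
  regularization.

The agent blends both outputs per joint with spherical linear interpolation

    q(w) = q_follow · exp( w · log(q_follow⁻¹ q_lead) )

with lead-weight `w = 0.1` when following and `w = 0.9` when leading.
During improvisation a binary role coefficient is redrawn every 4 s
(switch probability starts at 50%, grows by 1% per decision while following
dominates the recent past, resets upon becoming leader), and an inter-hand
distance above 0.3 scene units forces following immediately.

The analysis side computes, per trial: speed `v(t) = ‖s(t+Δt) − s(t)‖` of
the 4 Hz low-passed hand track, acceleration, between-player differences
`Δv̄, Δā`, hand distance `d(t)`; WTLCC (window 300 frames, step 50, lags
within ±90) with the mean absolute lag `t̂` and the follow-time ratio
`r_LF = ½(1 + mean sgn(lag)) · 100%`; Turing-test rates
`FNR = mean ε over artificial-partner trials`,
`FPR = mean ε over human-partner trials` with `ε = |s − s̃|`; and the
follow-net sensitivity matrix: geodesic output displacement
`d(q, q') = |log(q'/q)|` after freezing one leader joint in the input
window.

## Worked example

Recovering a known leader–follower delay from synthetic motion
(`examples/02_dyad_lag_recovery.py`):

```bash
$ python examples/02_dyad_lag_recovery.py
windows analyzed:  63
t_hat = 20.0 frames = 222 ms  (true delay 20 frames)
r_LF (follower focal) = 100.0 %  (always following)
r_LF (leader focal)   = 0.0 %  (always leading)
```

A follower built as a 20-frame-delayed copy of a band-limited leader is
analyzed blind: the mean absolute WTLCC lag recovers the 222 ms delay
exactly, and the sign convention puts the follower at `r_LF = 100%` and the
leader at 0% — the two extremes the ratio is designed to flag.

Training the follow-net on identity-coupled dyads
(`examples/03_follow_net_training.py`) reaches a held-out mean per-joint
geodesic error of 0.038 rad (about 4° of rotation), and the sensitivity
analysis (`examples/05_turing_and_sensitivity.py`) then shows
diagonal-dominant coupling — each leader joint drives its anatomical
counterpart in the follower:

```text
                left_hand  left_forearm  left_upper_arm  left_shoulder
left_hand           0.146         0.004           0.006          0.005
left_forearm        0.003         0.095           0.004          0.004
left_upper_arm      0.005         0.004           0.057          0.004
left_shoulder       0.006         0.009           0.009          0.219
```

The remaining examples cover quaternion pre-processing (`01`), the
improvising agent with role statistics (`04`), and there is a thin CLI
(`mirrorgame synth / train-follow / train-lead / simulate / analyze /
run-all`) over the same library functions.

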