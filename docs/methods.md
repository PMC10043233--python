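# Methods

`stopnet` implements an EEG brain–machine interface that detects a walking
person's intention to stop at an unexpected obstacle and, in a closed loop,
would issue the stop command to a lower-limb exoskeleton.  This note
documents the model, the defaults, the synthetic test bed, and the numerical
and design choices behind them.

## Signal model and preprocessing

Sessions hold 27 scalp channels (10-10 layout) and 4 EOG reference channels
at 500 Hz, in microvolts.  The chain is strictly causal — every stage
processes sample *n* using only samples ≤ *n* — because the decoder must run
in real time:

1. **Ocular artifact removal (H∞ adaptive filter).**  For each EEG channel
   the reference vector r(n) holds the four EOG samples plus a constant
   drift regressor; the channel's weight vector w(n) is updated by an
   H∞-optimal recursion and the cleaned sample is the a-priori error
   d(n) − wᵀr(n).  The Riccati update is kept in rank-1 (Sherman–Morrison)
   form with a feasibility guard on 1 − γ⁻² rᵀPr > 0; because r(n) is shared
   by all channels, one gain/covariance recursion serves all 27 weight
   vectors, vectorizing the per-sample update.  Defaults: γ = 1.15
   (robustness bound; closer to 1 = more aggressive), q = 1e−10 (adaptation
   rate added to P each sample), P₀ = 0.01·I, drift regressor on.  The first
   15 s of a session are treated as convergence time (subjects stand still
   during them) and flagged, never deleted.
2. **Four-band decomposition.**  Second-order state-variable band-pass
   filters at 0.4–3, 2–4, 3–6 and 5–8 Hz — analog prototype
   H(s) = Bs/(s² + Bs + ω₀²) with B and ω₀ fixed by the band edges,
   discretized by the bilinear transform with edge prewarping.  Filter state
   persists across calls, so chunked (online) and one-shot processing are
   bit-identical; a prefix of the input always yields a prefix of the
   output.  The stop-band magnitudes at 25 Hz implied by this design are
   0.104 / 0.081 / 0.123 / 0.127 for the four bands; tests assert the
   implemented digital response against the analytic prototype, not against
   a round number.
3. **Epochs.**  Sliding windows of 0.6 s at a 0.1-s stride (300 samples /
   50 samples at 500 Hz); epoch count over a signal of n samples is
   ⌊(n − 300)/50⌋ + 1.  Epochs are not baseline-corrected or z-scored; raw
   filtered microvolts feed the network (a config flag can enable
   train-set-only standardization, off by default).

**Labels.**  Repetition = one laser (obstacle) onset plus the stop cue 1–2 s
later.  Wide labeling: an epoch is *stop* (class 2) when ≥ 0.4 of its 0.6 s
lies in [laser − 0.2 s, stop cue], else *walk* (class 1) when ≥ 0.4 s lies
in [laser − 8 s, laser + 0.2 s]; epochs qualifying for both take class 2
(the stimulus-locked activity is the detection target); epochs touching a
discard window are unlabeled.  NN1-training labeling: exactly the 4 epochs
ending at/before the laser and the 4 starting at/after it — 0.9 s per side,
a balanced 4/4 per repetition.

## The cascade

Both networks share one architecture on a 108 × 300 input (4 bands × 27
channels stacked on the spatial axis, time on the other — the only layout
under which a 64×2 first kernel followed by 1×k kernels is coherent):

    conv 64×2 (6 filters) – BN – ReLU – maxpool 1×2
    conv 1×11 (12)        – BN – ReLU – maxpool 1×2
    conv 1×10 (12)        – BN – ReLU – maxpool 1×2
    dropout (0.5) – FC 60 – ReLU – FC 2 – softmax

Convolutions are unpadded; pooling has floor semantics; every layer's output
shape is therefore exactly computable (audited in tests).  Training: SGD
with momentum 0.9, lr 0.01 with ×0.1 staircase drops every 10 epochs, L2
10⁻⁴ on conv/FC weights, batch 100, up to 500 epochs, fully seeded.  The
network and its training loop are implemented directly on numpy (float32,
im2col/Toeplitz GEMM formulations of the convolutions); layer gradients are
verified against central differences in the test suite, and training is
bit-reproducible for a fixed seed and BLAS.

**NN1** trains on the laser-locked 4+4 epochs of the training trials.
**Harvest:** NN1 is replayed over the wide-window epochs of those same
trials; its stop-classified epochs split into *false stops* (truly walk)
and *true stops* (truly stop).  The majority side is randomly undersampled
to the minority count (seeded), and the balanced set trains **NN2** with the
same architecture and training parameters — false stop → walk, true stop →
stop.  Inference: NN1 gates NN2 (an epoch NN1 calls walk never reaches
NN2); the final output enters a 5-deep FIFO and a stop **command** fires
when ≥ 3 of the last 5 outputs are stops (identically: their mode).  The
cascade's stop outputs are by construction a subset of NN1's, so FP/min and
TP can only decrease — the veto direction.  No command is issued until the
buffer holds 5 outputs; after a latched (close-loop) stop the buffer clears
at the next repetition.

Ties at exactly (0.5, 0.5) resolve to walk, the conservative output for a
device that should not stop spuriously.

## Evaluation

Per repetition: the walking window is [laser − 8 s, laser − 0.2 s] clipped
to the trial start and minus discard windows; FP = stop command in it; TP =
stop command in [laser, stop cue]; commands inside the repetition span but
in neither window (discard windows, the ±0.2-s transition) count as FP —
the conservative reading.  Aggregates: NOFP% (repetitions with zero FP),
TP% (repetitions with a TP; under close-loop latch semantics only
repetitions that survived the walking phase are eligible, and an empty
eligible set reports TP% as undefined, not 0), NOFP/TP% (both), FP/min =
60·ΣFP/Σ(walking time), SuFP = mean time to the first FP over repetitions
containing one.  **FP/min denominator:** labeled walking time summed over
scored repetitions, not wall-clock session time — stopped and discarded
periods must not dilute the rate.  This choice is prominent because the
magnitude of FP/min depends on it; a wall-clock denominator is available
(`aggregate(..., denominator="wallclock")`) for sensitivity checks.
Cross-validation is leave-one-trial-out with equal fold weights.

## Transfer learning + fine-tuning

For a target subject with few repetitions: pre-train NN1 on the pooled
laser-locked epochs of all source sessions plus the target's first 20
training repetitions, run the harvest over the same pooled material, train
NN2; then fine-tune both networks on the target-only material — all layers
trainable, lr 0.001 (one decade below pre-training), 50 epochs by default —
re-running NN2's harvest with the fine-tuned NN1 on the target repetitions
only.  The fine-tuning hyperparameters and the no-freezing policy are this
package's defaults (the procedure itself fixes neither); both are
config-exposed.  A degenerate re-harvest falls back to the pooled NN2 with
a warning.  Repetition provenance is stored in every model so leakage of
target test trials is auditable.

## Synthetic sessions

The generator reproduces the protocol layouts exactly: treadmill 9 trials ×
9 repetitions (81), exoskeleton 8 × 5 (40) with a 4-s post-activation
discard after each stop, patient 4 × 5 (20) with 6–8-s gaps; 120-s trials,
laser gaps 10–12 s (6–8 s for patients), stop latency uniform 1–2 s, 15-s
lead-in rest.  Laser count per trial is capped at the protocol value, so
the totals hold for every seed.

EEG = 1/f background (per-channel rms 5 µV) + blink artifacts mixed from an
EOG source (blink rate 0.15 Hz, 120 µV, per-channel mixing gains 0.05–0.2)
+ a step-locked gait artifact (1.8 Hz + harmonic, ~3 µV) + the evoked
response at each laser.  The response template is a positive cos² bump
(peak 0.35 s, width 0.3 s) plus a slower windowed 1.5-Hz deflection, so all
four analysis bands carry signal; per-repetition amplitude (±15%) and
latency (±30 ms) jitter emulate single-trial variability.  The template is
identically zero before the laser.  Foot IMU traces (100 Hz) carry
alternating step impulses (~0.5 g) while walking and a strong deceleration
impulse (~2.5 g) at each foot's stop; the later foot defines the stop cue.
Traces emulate gravity-compensated (linear) acceleration so the 1-g
detection threshold is meaningful without a gravity-removal stage.

What the generator does **not** emulate: volume conduction and realistic
topographies, non-stationary background statistics, movement artifacts
correlated with the evoked response, or real inter-subject variability
structure.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative behavior (veto direction,
transfer-learning benefit) emerges under controlled conditions — not that
the reported human-EEG performance numbers would be reproduced.

## Test problem sizes

The system-level suites run on deliberately scaled-down conditions chosen
as this package's test budget: end-to-end recovery uses 3 trials × 5
repetitions at 250 Hz (66-s trials), a high-SNR evoked response (20 µV
bump, 12 µV slow wave over 5 µV noise), and 25 training epochs; the
transfer-learning property uses 150-Hz patient-style sessions (2 source
subjects × 4 repetitions, target 2 × 3), 10 training epochs and an 8-epoch
fine-tune, with the target drawn from a +100-ms / 0.8× shifted response
distribution.  The network's temporal input dimension follows the epoch
length (0.6 s × fs), which the architecture accommodates; at 500 Hz the
input is the canonical 108 × 300.  Thresholds and directions asserted by
the tests are not scaled.

## Numerical and degenerate-input choices

* Sample indexing is 0-based with half-open intervals; clock mapping
  between IMU and EEG rates is round-half-up and order-preserving.
* The H∞ update skips the covariance inflation step on samples where the
  feasibility condition fails (numerically near-singular); with a zero EOG
  reference and the drift regressor off, the filter is exactly the
  identity.
* IMU peak = strictly greater than its left neighbor and ≥ its right
  neighbor (plateaus take their first sample); the envelope low-pass is a
  causal 2nd-order Butterworth at 8 Hz, whose ~30-ms group delay keeps
  labeling error within the 50-ms accuracy the pipeline assumes.
  Repetitions with no qualifying peak are flagged for manual review, never
  guessed.
* Signals shorter than one epoch yield an empty epoch sequence, not an
  error; a repetition too close to a trial edge for the 0.9-s spans is
  skipped with a warning; a repetition without a stop cue contributes walk
  epochs only.
* A harvest with an empty class raises a dedicated degeneracy error (NN2
  is untrainable); balanced harvests smaller than the batch size shrink the
  batch with a warning.
* EDF+ storage is int16 (quantization bounded by the written physical
  range); BrainVision is float32.  Round-trips are tested against the mne
  readers.

## Known limitations

* The CNN runs on numpy; it is CPU-only and, while GEMM-formulated, far
  from framework speed — fine for the repetition counts this method needs
  (tens per subject), not for large-scale training.
* The H∞ parameters are defaults, not fitted values; real sessions may need
  per-lab tuning of γ and q.
* Close-loop latch semantics are simulated on pre-recorded streams; true
  feedback effects (the subject reacting to the device stopping) are out of
  reach of any offline replay.
* The exact FP/min denominator used in the original reports is not
  recoverable from the metric definitions alone; see the evaluation section
  for why labeled walking time is used and how to switch.
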