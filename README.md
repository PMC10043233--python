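# stopnet

An EEG brain–machine interface that detects a walking person's intention to
stop when an unexpected obstacle appears — the signal a lower-limb
exoskeleton needs to halt before a collision.  The package is for BCI /
neural-engineering researchers who want a complete, testable implementation
of the method: the causal preprocessing chain, the two-stage convolutional
cascade with its false-positive veto, the pseudo-online evaluation metrics,
transfer learning with subject fine-tuning, IMU-based stop labeling,
standard-format session I/O, and a synthetic session generator that makes
every stage verifiable without human recordings.

## The method

A single-trial detector must fire within the 1–2 s between the obstacle
(laser) onset and the actual stop while staying silent over minutes of
walking — the hard part is the false-positive rate, not the detection.  The
pipeline:

1. **Causal preprocessing.**  H∞ adaptive filtering removes
   EOG-correlated (ocular) activity sample-by-sample from each of the 27
   channels, using the 4 EOG electrodes plus a drift regressor as
   reference.  Four second-order state-variable band-pass filters split the
   cleaned signal into 0.4–3, 2–4, 3–6 and 5–8 Hz — the bands where the
   stimulus-locked potentials (P300-, error- and visual-evoked) live.
   Epochs of 0.6 s are cut at a 0.1-s stride.
2. **NN1 — stop detector.**  A CNN (conv 64×2/6 → 1×11/12 → 1×10/12, each
   with batch-norm + ReLU + 1×2 max-pool; dropout; FC 60; FC 2; softmax) on
   the 108 × 300 band×channel × time epoch, trained on the 4 epochs before
   and 4 after each laser (0.9 s per side), with SGD momentum 0.9, lr 0.01
   (×0.1 every 10 epochs), L2 10⁻⁴, batch 100.
3. **NN2 — false-stop veto.**  NN1 is replayed over wide windows of its own
   training trials (walk = [−8, 0.2] s, stop = [−0.2 s, stop cue], ≥0.4-s
   overlap rule); its false and true stop detections, balanced by random
   undersampling, train a second identical network that re-classifies every
   epoch NN1 calls "stop".
4. **Command rule.**  A stop command is issued only when ≥ 3 of the last 5
   cascade outputs are stops (the mode of the buffer).  In close-loop
   semantics the first command ends the repetition.
5. **Metrics.**  Per repetition: NOFP (no false positive), TP (a command in
   [laser, stop]), NOFP/TP (both), FP/min (false commands per minute of
   walking time), SuFP (time to first failure).  Leave-one-trial-out
   cross-validation, macro-averaged.
6. **TL + FT.**  For a new subject with only ~20 repetitions: pre-train on
   pooled source subjects + the target's repetitions, then fine-tune both
   networks on the target's repetitions alone (lr ×0.1, all layers
   trainable).

Because the cascade can only remove stop outputs, FP/min and TP are
monotonically non-increasing from NN1 to NN1+NN2 — the design trades a
little sensitivity for a large cut in false stops.

## Worked example

`examples/03_cascade_pseudo_online.py` generates a scaled high-SNR
synthetic session (3 trials × 5 repetitions at 250 Hz), trains NN1 on two
trials, harvests its false stops to train NN2, and replays the held-out
trial pseudo-online:

```
NN1 train accuracy: 0.91  harvest (false, true stops): (96, 96)

held-out trial, pseudo-online:
                NN1 only   NN1+NN2
TP %               100.0     100.0
NOFP %               0.0       0.0
NOFP/TP %            0.0       0.0
FP/min             400.0      38.5
```

Reading: NN1 alone detects every stop but fires constantly during walking
(400 false commands per walking minute); the veto network removes ~90% of
those while keeping every true detection — the qualitative behavior the
two-stage design exists for.  (On this seed a few false positives survive in
every repetition, so NOFP stays at 0 even though the rate drops tenfold;
other seeds reach NOFP > 0.)  The other examples cover session generation
(`01`), IMU stop labeling (`02`), transfer learning + fine-tuning (`04`)
and standard-format I/O (`05`).

A thin CLI covers the shell-friendly pieces:

```bash
stopnet synth --variant treadmill --seed 1 --out session/
stopnet label-stops --session session/manifest.yaml --review-csv stops.csv
stopnet evaluate --session session/manifest.yaml --mode pseudo
```

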