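"""Label the actual stop moment of each repetition from the foot IMUs.

Per foot the acceleration modulus is low-pass filtered and the first peak
above 1 g within 2 s of the laser marks that foot's stop; the later foot
defines the repetition's stop cue, mapped from the 100-Hz IMU clock onto
the 500-Hz EEG clock.  The printed error is the difference between the
recovered cue and the generator's ground truth.
"""

from stopnet import synth
from stopnet.imu_stop import label_stops

p = synth.ProtocolSpec.preset("treadmill", n_trials=2, reps_per_trial=4,
                              trial_len_s=55.0)
session = synth.generate_session(p, seed=2)
fs = session.recording.fs

detections = label_stops(session.imu["left"], session.imu["right"],
                         session.events.laser_onsets, fs)

print("rep  laser_s  detected_stop_s  truth_s  error_ms  review")
for rep, det in enumerate(detections):
    laser = session.events.laser_onsets[rep] / fs
    truth = session.truth.loc[rep, "stop_s"]
    if det.stop_cue is None:
        print(f"{rep:3d}  {laser:7.2f}  {'-':>15}  {truth:7.2f}  {'-':>8}  yes")
        continue
    got = det.stop_cue / fs
    print(f"{rep:3d}  {laser:7.2f}  {got:15.3f}  {truth:7.3f}  "
          f"{1000 * (got - truth):8.1f}  {'yes' if det.needs_review else 'no'}")
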