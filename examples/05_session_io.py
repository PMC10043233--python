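"""Write a session to standard formats and read it back.

EEG + events go to a BrainVision triplet (or EDF+); the IMU traces to CSV;
a YAML manifest ties the files together with the channel-role and marker
maps.  The printed maximum error shows the storage quantization (float32
for BrainVision, int16 for EDF+).
"""

import tempfile
from pathlib import Path

import numpy as np

from stopnet import io_formats, synth

p = synth.ProtocolSpec.preset("treadmill", n_trials=1, reps_per_trial=3,
                              trial_len_s=45.0)
session = synth.generate_session(p, seed=4, keep_components=False)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    for dialect, name in [("brainvision", "session.vhdr"), ("edf", "session.edf")]:
        io_formats.write_recording(session.recording, session.events,
                                   tmp / name, dialect=dialect)
        rec, ev = io_formats.read_recording(tmp / name)
        n = session.recording.n_samples
        err = np.abs(rec.eeg[:, :n] - session.recording.eeg).max()
        print(f"{dialect:12} max signal error {err:.2e} uV, "
              f"{len(ev.laser_onsets)} lasers, "
              f"{len(ev.trial_bounds)} trial(s) preserved")

    for side, trace in session.imu.items():
        io_formats.write_imu_csv(trace, tmp / f"imu_{side}.csv")
    io_formats.write_manifest(tmp / "manifest.yaml", "session.vhdr", "brainvision",
                              {s: f"imu_{s}.csv" for s in session.imu},
                              eeg_channels=session.recording.channel_names,
                              eog_channels=session.recording.eog_names)
    rec, ev, imus = io_formats.read_session(tmp / "manifest.yaml")
    print(f"manifest     reloaded {rec.eeg.shape[0]} EEG + {rec.eog.shape[0]} EOG "
          f"channels and {len(imus)} IMU traces")
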