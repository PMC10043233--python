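"""Generate a protocol-conformant synthetic session and inspect it.

The treadmill protocol is 9 trials x 9 laser repetitions (81 total); each
laser is followed 1-2 s later by the subject's actual stop.  The SNR table
shows how much evoked-response power each analysis band carries relative to
the background (power ratio; >1 means the band is signal-dominated in the
post-laser window).
"""

from stopnet import synth

session = synth.generate_session(synth.ProtocolSpec.preset("treadmill"), seed=1)

print(f"repetitions: {session.events.n_repetitions}")
print(f"trials:      {len(session.events.trial_bounds)}")
print(f"duration:    {session.recording.duration_s:.0f} s of "
      f"{session.recording.eeg.shape[0]}-channel EEG at {session.recording.fs:g} Hz")
print()
print("per-band SNR of the evoked response (default amplitudes):")
print(synth.snr_report(session).round(3).to_string(index=False))
print()
print("ground truth (first repetitions):")
print(session.truth.head(5).round(3).to_string(index=False))
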