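"""Causal cleaning chain: H-infinity ocular removal, the four-band filter
bank, sliding-epoch extraction and walk/stop labeling."""

import numpy as np
import pytest
from scipy import signal as sps

from stopnet.core import EventLog, Recording
from stopnet.preprocessing import (
    BAND_EDGES,
    BandStack,
    BandpassBank,
    HinfConfig,
    band_frequency_response,
    bandpass_bank,
    design_band_sos,
    extract_epochs,
    label_epochs,
    remove_ocular_artifacts,
)

FS = 500.0


def _recording(eeg, eog, fs=FS):
    names = [f"ch{i}" for i in range(eeg.shape[0])]
    return Recording(eeg, eog, fs, names, [f"EOG{i+1}" for i in range(eog.shape[0])])


class TestHinf:
    def test_zero_eog_without_drift_is_identity(self, rng):
        eeg = rng.standard_normal((3, 2000))
        rec = _recording(eeg, np.zeros((4, 2000)))
        res = remove_ocular_artifacts(rec, HinfConfig(drift=False))
        np.testing.assert_array_equal(res.recording.eeg, eeg)

    def test_stationary_mixing_removed(self, rng):
        """EEG contaminated by 0.8 x EOG1: after the 15-s settling span the
        residual EOG-correlated power must drop by >= 10x."""
        n = int(25 * FS)
        clean = rng.standard_normal((2, n))
        eog = rng.standard_normal((4, n)) * 50.0
        eeg = clean + 0.8 * eog[0]
        rec = _recording(eeg, eog)
        res = remove_ocular_artifacts(rec, HinfConfig())
        tail = slice(int(15 * FS), n)
        e1 = eog[0, tail]
        beta_out = np.dot(res.recording.eeg[0, tail], e1) / np.dot(e1, e1)
        assert beta_out**2 <= 0.8**2 / 10.0

    def test_drift_regressor_absorbs_offset(self):
        n = int(20 * FS)
        eeg = np.full((1, n), 40.0)
        rec = _recording(eeg, np.zeros((4, n)))
        res = remove_ocular_artifacts(rec, HinfConfig(p0=1.0))
        last_second = res.recording.eeg[0, -int(FS):]
        assert abs(last_second.mean()) < 0.5  # started at 40 uV

    def test_wrong_eog_count_rejected(self, rng):
        rec = _recording(rng.standard_normal((2, 100)), rng.standard_normal((3, 100)))
        with pytest.raises(ValueError, match="4 EOG"):
            remove_ocular_artifacts(rec)

    def test_settling_span_flagged_not_deleted(self, rng):
        n = int(16 * FS)
        rec = _recording(rng.standard_normal((1, n)), np.zeros((4, n)))
        res = remove_ocular_artifacts(rec)
        assert res.recording.n_samples == n
        assert res.settle_samples == int(15 * FS)


class TestBandBank:
    def test_digital_response_matches_analytic_prototype(self):
        """Criterion: the implemented filters track the analytic state-variable
        band-pass transfer function across the band and stop regions."""
        freqs = np.concatenate([np.linspace(0.2, 10, 50), [15.0, 25.0]])
        for low, high in BAND_EDGES:
            sos = design_band_sos(low, high, FS)
            _, h = sps.sosfreqz(sos, worN=freqs, fs=FS)
            analytic = band_frequency_response(low, high, freqs)
            np.testing.assert_allclose(np.abs(h), analytic, atol=0.02)

    @pytest.mark.parametrize("low, high", BAND_EDGES)
    def test_center_passband_gain(self, low, high):
        """A sinusoid at the band center passes with amplitude >= 0.7."""
        f0 = np.sqrt(low * high)
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        rec = _recording(x, np.zeros((1, len(t))))
        out = bandpass_bank(rec).data[BAND_EDGES.index((low, high)), 0]
        steady = out[int(20 * FS):]
        assert steady.max() >= 0.7

    def test_dc_rejected_everywhere(self):
        n = int(30 * FS)
        rec = _recording(np.ones((1, n)) * 100.0, np.zeros((1, n)))
        out = bandpass_bank(rec).data
        assert np.abs(out[:, 0, -int(FS):]).max() <= 100 * 0.01

    def test_25hz_stopband(self):
        """Attenuation at 25 Hz per band, frozen from the analytic response
        (0.104, 0.081, 0.123, 0.127 for the four bands)."""
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 25.0 * t)[None, :]
        rec = _recording(x, np.zeros((1, len(t))))
        out = bandpass_bank(rec).data
        expected = [0.104, 0.081, 0.123, 0.127]
        for b, exp in enumerate(expected):
            amp = np.abs(out[b, 0, -int(5 * FS):]).max()
            assert amp == pytest.approx(exp, abs=0.01)
            assert amp <= 0.15

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_band_sos(5, 8, fs=15.0)

    def test_streaming_equals_batch(self, rng):
        """Filter state persists across chunks: chunked processing reproduces
        the one-shot output exactly (online/pseudo-online equivalence)."""
        x = rng.standard_normal((3, 4000))
        full = BandpassBank(3, FS).process(x)
        bank = BandpassBank(3, FS)
        parts = [bank.process(x[:, i : i + 700]) for i in range(0, 4000, 700)]
        np.testing.assert_allclose(np.concatenate(parts, axis=2), full, rtol=1e-10)

    def test_causality_prefix_property(self, rng):
        """Truncating the input never changes already-emitted samples."""
        x = rng.standard_normal((2, 3000))
        full = BandpassBank(2, FS).process(x)
        for n in (50, 1234, 2999):
            pre = BandpassBank(2, FS).process(x[:, :n])
            np.testing.assert_array_equal(pre, full[:, :, :n])


def _stack(n_samples, fs=FS, n_ch=2):
    return BandStack(np.zeros((4, n_ch, n_samples)), fs)


class TestExtractEpochs:
    @pytest.mark.parametrize(
        "dur_s, expected",
        [(0.6, 1), (2.0, 15), (0.59, 0), (0.7, 2), (10.0, 95)],
    )
    def test_count_examples(self, dur_s, expected):
        eps = extract_epochs(_stack(int(round(dur_s * FS))))
        assert len(eps) == expected

    def test_count_formula_random_durations(self, rng):
        """count = floor((n - 300) / 50) + 1 on 100 random durations."""
        for _ in range(100):
            n = int(rng.integers(1, 20000))
            eps = extract_epochs(_stack(n))
            expected = 0 if n < 300 else (n - 300) // 50 + 1
            assert len(eps) == expected

    def test_starts_on_stride_grid(self):
        eps = extract_epochs(_stack(1000))
        assert list(eps.starts) == [0, 50, 100, 150, 200, 250, 300, 350, 400,
                                    450, 500, 550, 600, 650, 700]


class TestLabelEpochs:
    def _events(self, laser=10000, stop=None, n=20000, discard=()):
        stop = laser + 1000 if stop is None else stop
        return EventLog([laser], [stop], [(0, n)], list(discard))

    def _labeled(self, **kw):
        eps = extract_epochs(_stack(kw.pop("n", 20000)))
        return label_epochs(eps, self._events(**kw))

    def test_class2_needs_04s_overlap(self):
        """Epoch [laser-0.5, laser+0.1]: stop-window overlap is only 0.3 s,
        so it stays class 1."""
        lab = self._labeled()
        i = list(lab.starts).index(10000 - 250)
        assert lab.labels[i] == 1

    def test_class2_when_covered(self):
        """Epoch [laser+0.1, laser+0.7] with stop at laser+2 s: fully inside
        the stop window -> class 2."""
        lab = self._labeled()
        i = list(lab.starts).index(10000 + 50)
        assert lab.labels[i] == 2

    def test_tie_break_prefers_stop(self):
        """Epoch [laser-0.4, laser+0.2] qualifies for both classes (0.6 s in
        the walk window, exactly 0.4 s in the stop window) -> class 2."""
        lab = self._labeled()
        i = list(lab.starts).index(10000 - 200)
        assert lab.labels[i] == 2

    def test_walk_window_limited_to_8s(self):
        """Class-1 epochs must hold >= 0.4 s of [laser-8, laser+0.2]; the
        earliest admissible start is therefore laser - 8.2 s."""
        lab = self._labeled()
        starts = lab.starts[lab.labels == 1]
        assert starts.min() == 10000 - int(8.2 * FS)

    def test_discard_window_unlabels(self):
        lab = self._labeled(discard=[(8000, 9000)])
        overlapping = (lab.starts < 9000) & (lab.starts + 300 > 8000)
        assert np.all(lab.labels[overlapping] == 0)

    def test_missing_stop_cue_warns_and_keeps_walk(self):
        eps = extract_epochs(_stack(20000))
        ev = EventLog([10000], [-1], [(0, 20000)])
        with pytest.warns(UserWarning, match="no stop cue"):
            lab = label_epochs(eps, ev)
        assert np.all(lab.labels != 2)
        assert np.any(lab.labels == 1)

    def test_nn1_mode_yields_balanced_8(self):
        """One repetition -> exactly 4 walk + 4 stop laser-locked epochs
        spanning 0.9 s on each side of the stimulus."""
        eps = extract_epochs(_stack(20000))
        lab = label_epochs(eps, self._events(), mode="nn1_train")
        assert len(lab) == 8
        assert (lab.labels == 1).sum() == 4 and (lab.labels == 2).sum() == 4
        walk = lab.starts[lab.labels == 1]
        stop = lab.starts[lab.labels == 2]
        span = int(0.9 * FS)
        assert walk.min() == 10000 - span and walk.max() + 300 == 10000
        assert stop.min() == 10000 and stop.max() + 300 == 10000 + span

    def test_four_consecutive_epochs_span_09s(self):
        """4 x 0.1-s strides + 0.6 s epoch = 0.9 s exactly."""
        eps = extract_epochs(_stack(1000))
        starts = eps.starts[:4]
        assert (starts[3] + eps.epoch_len) - starts[0] == int(0.9 * FS)

    def test_nn1_mode_skips_edge_repetitions(self):
        eps = extract_epochs(_stack(5000))
        ev = EventLog([250], [750], [(0, 5000)])  # laser 0.5 s into trial
        with pytest.warns(UserWarning, match="trial edge"):
            lab = label_epochs(eps, ev, mode="nn1_train")
        assert len(lab) == 0

    def test_nn1_mode_balanced_per_repetition(self, small_session):
        from stopnet.preprocessing import preprocess

        stack = preprocess(small_session.recording)
        eps = extract_epochs(stack)
        lab = label_epochs(eps, small_session.events, mode="nn1_train")
        for rep in np.unique(lab.rep_ids):
            sel = lab.rep_ids == rep
            assert (lab.labels[sel] == 1).sum() == 4
            assert (lab.labels[sel] == 2).sum() == 4
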