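"""Cascade logic: NN1 dataset construction, harvest/balance, the 3-of-5
decision buffer, stream replay semantics and the veto-subset property."""

import itertools

import numpy as np
import pytest

from stopnet import synth
from stopnet.cascade import (
    BUFFER_LEN,
    CascadeDegeneracyError,
    DecisionBuffer,
    HarvestSet,
    balance_harvest,
    build_nn1_dataset,
    cascade_step,
    nn1_prediction_pass,
    run_stream,
)
from stopnet.core import EventLog
from stopnet.preprocessing import BandStack, extract_epochs, label_epochs

FS = 500.0


class StubClassifier:
    """Content-threshold classifier: 'stop' iff the epoch mean exceeds a
    threshold.  With indicator-valued stack data this is an exact oracle."""

    def __init__(self, threshold):
        self.threshold = threshold

    def predict_classes(self, x):
        means = x.reshape(x.shape[0], -1).mean(axis=1)
        return np.where(means > self.threshold, 2, 1)


class ConstantClassifier:
    def __init__(self, label):
        self.label = label

    def predict_classes(self, x):
        return np.full(x.shape[0], self.label)


class ExplodingClassifier:
    def predict_classes(self, x):
        raise AssertionError("should never be consulted")


def _indicator_session(n=30000, laser=20000, stop=21000):
    """Stack whose value is 1 exactly inside the stop-class window
    [laser - 0.2 s, stop], 0 elsewhere: epoch means encode the true label."""
    data = np.zeros((4, 2, n))
    data[:, :, laser - 100 : stop + 1] = 1.0
    events = EventLog([laser], [stop], [(0, n)])
    return BandStack(data, FS), events


class TestDecisionBuffer:
    def test_three_of_five_equals_mode(self):
        """Exhaustive over all 2^5 buffer states: the >= 3-of-5 command rule
        is exactly the mode of the five binary outputs."""
        for bits in itertools.product([1, 2], repeat=BUFFER_LEN):
            buf = DecisionBuffer()
            for b in bits:
                buf.push(b)
            n_stop = sum(1 for b in bits if b == 2)
            mode_is_stop = n_stop > BUFFER_LEN - n_stop
            assert buf.command == (n_stop >= 3) == mode_is_stop

    def test_no_command_before_five_outputs(self):
        buf = DecisionBuffer()
        for _ in range(4):
            assert buf.push(2) is False
        assert buf.push(2) is True

    def test_fifo_eviction(self):
        buf = DecisionBuffer()
        for b in (2, 2, 2, 1, 1):
            buf.push(b)
        assert buf.command  # 3 stops of 5
        buf.push(1)  # evicts the oldest stop -> 2 stops
        assert not buf.command


class TestCascadeStep:
    def test_nn1_walk_short_circuits(self, rng):
        """When NN1 says walk, NN2 is never consulted."""
        buf = DecisionBuffer()
        x = rng.standard_normal((4, 2, 300)).astype(np.float32)
        out, cmd = cascade_step(ConstantClassifier(1), ExplodingClassifier(), x, buf)
        assert out == 1 and cmd is False

    def test_nn2_vetoes_false_stop(self, rng):
        buf = DecisionBuffer()
        x = rng.standard_normal((4, 2, 300)).astype(np.float32)
        out, _ = cascade_step(ConstantClassifier(2), ConstantClassifier(1), x, buf)
        assert out == 1

    def test_command_after_three_stops(self, rng):
        buf = DecisionBuffer()
        x = rng.standard_normal((4, 2, 300)).astype(np.float32)
        results = [cascade_step(ConstantClassifier(2), ConstantClassifier(2), x, buf)
                   for _ in range(5)]
        assert [cmd for _, cmd in results] == [False] * 4 + [True]


class TestNN1Dataset:
    def test_counts_are_8_per_repetition(self, small_session):
        from stopnet.preprocessing import preprocess

        stack = preprocess(small_session.recording)
        ds = build_nn1_dataset(stack, small_session.events)
        assert len(ds) == small_session.events.n_repetitions * 8

    def test_trial_restriction(self, small_session):
        from stopnet.preprocessing import preprocess

        stack = preprocess(small_session.recording)
        ds = build_nn1_dataset(stack, small_session.events, trials=[0])
        reps0 = set(small_session.events.repetitions_in_trial(0))
        assert set(ds.rep_ids) == {int(r) for r in reps0}


class TestHarvest:
    def test_always_stop_harvests_everything(self):
        """An always-stop NN1 turns every labeled epoch into harvest: all
        class-1 epochs become false stops, all class-2 ones true stops."""
        stack, events = _indicator_session()
        h = nn1_prediction_pass(ConstantClassifier(2), stack, events)
        wide = label_epochs(extract_epochs(stack), events)
        n_walk = int((wide.labels == 1).sum())
        n_stop = int((wide.labels == 2).sum())
        assert h.counts == (n_walk, n_stop)

    def test_oracle_nn1_is_degenerate(self):
        """A perfect NN1 leaves no false stops -> NN2 cannot be trained."""
        stack, events = _indicator_session()
        oracle = StubClassifier(threshold=0.4 / 0.6 - 1e-6)
        with pytest.raises(CascadeDegeneracyError):
            nn1_prediction_pass(oracle, stack, events)

    def test_bernoulli_corruptor_counts(self):
        """NN1 modeled as the oracle with decisions flipped at rates
        (eps1, eps2) = (0.2, 0.1): harvested counts land inside the binomial
        95% envelope of their expectations."""
        stack, events = _indicator_session()
        wide = label_epochs(extract_epochs(stack), events)
        n_walk = int((wide.labels == 1).sum())
        n_stop = int((wide.labels == 2).sum())

        class Corruptor(StubClassifier):
            def __init__(self):
                super().__init__(0.4 / 0.6 - 1e-6)
                self.rng = np.random.default_rng(42)

            def predict_classes(self, x):
                truth = super().predict_classes(x)
                eps = np.where(truth == 1, 0.2, 0.1)
                flip = self.rng.random(len(truth)) < eps
                return np.where(flip, 3 - truth, truth)

        h = nn1_prediction_pass(Corruptor(), stack, events)
        nf, nt = h.counts
        for count, n, p in ((nf, n_walk, 0.2), (nt, n_stop, 0.9)):
            mean, sd = n * p, np.sqrt(n * p * (1 - p))
            assert abs(count - mean) <= 1.96 * sd + 1


class TestBalance:
    def _harvest(self, nf, nt):
        stack, events = _indicator_session()
        wide = label_epochs(extract_epochs(stack), events)
        return HarvestSet(wide, np.arange(nf), np.arange(100, 100 + nt))

    def test_undersample_to_minority(self):
        b = balance_harvest(self._harvest(120, 40), seed=0)
        assert b.counts == (40, 40)

    def test_already_balanced_unchanged(self):
        h = self._harvest(40, 40)
        b = balance_harvest(h, seed=0)
        np.testing.assert_array_equal(b.false_idx, h.false_idx)
        np.testing.assert_array_equal(b.true_idx, h.true_idx)

    def test_seeded_determinism(self):
        h = self._harvest(120, 40)
        b1 = balance_harvest(h, seed=5)
        b2 = balance_harvest(h, seed=5)
        np.testing.assert_array_equal(b1.false_idx, b2.false_idx)


def _multi_rep_session():
    p = synth.ProtocolSpec.preset("treadmill", n_trials=1, reps_per_trial=3,
                                  trial_len_s=45.0, lead_in_s=2.0, fs=FS)
    events, _ = synth.generate_events(p, seed=11)
    n = events.trial_bounds[-1][1] + 500
    data = np.zeros((4, 2, n))
    for laser, stop in zip(events.laser_onsets, events.stop_cues):
        data[:, :, laser - 100 : stop + 1] = 1.0
    return BandStack(data, FS), events


class TestRunStream:
    def test_all_walk_pair_is_silent(self):
        stack, events = _multi_rep_session()
        tl = run_stream(ConstantClassifier(1), ExplodingClassifier(), stack, events)
        assert not tl["command"].any()

    def test_oracle_pair_fires_once_per_repetition_in_window(self):
        """With oracle classifiers the latched stream issues exactly one stop
        command per repetition, inside [laser, stop + 0.5 s]."""
        stack, events = _multi_rep_session()
        oracle = StubClassifier(0.4 / 0.6 - 1e-6)
        tl = run_stream(oracle, ConstantClassifier(2), stack, events, latch=True)
        cmds = tl.loc[tl["command"], "t_end_s"].to_numpy()
        assert len(cmds) == events.n_repetitions
        for t, laser, stop in zip(cmds, events.laser_onsets, events.stop_cues):
            assert laser / FS <= t <= stop / FS + 0.5

    def test_latch_contract(self):
        """always-stop pair: latch=True fires once per repetition span while
        latch=False fires on every buffered epoch."""
        stack, events = _multi_rep_session()
        pair = (ConstantClassifier(2), ConstantClassifier(2))
        tl_latch = run_stream(*pair, stack, events, latch=True)
        tl_free = run_stream(*pair, stack, events, latch=False)
        n_latch = int(tl_latch["command"].sum())
        n_free = int(tl_free["command"].sum())
        assert n_latch == events.n_repetitions + 1  # one extra after last stop
        assert n_free > 3 * n_latch

    def test_veto_subset_property(self):
        """Cascade stop outputs are a subset of NN1 stop outputs, for any
        NN1/NN2 pair (random pairs over 10 streams)."""
        stack, events = _multi_rep_session()
        for seed in range(10):
            r = np.random.default_rng(seed)

            class RandomClf:
                def __init__(self, p, rng):
                    self.p, self.rng = p, rng

                def predict_classes(self, x):
                    return np.where(self.rng.random(x.shape[0]) < self.p, 2, 1)

            tl = run_stream(RandomClf(0.4, r), RandomClf(0.5, r), stack, events)
            stop_final = tl["final"] == 2
            stop_nn1 = tl["nn1"] == 2
            assert (stop_final & ~stop_nn1).sum() == 0

    def test_leakage_audit(self, small_session):
        """No test-trial repetitions appear in either training provenance."""
        from stopnet import cnn
        from stopnet.cascade import train_cascade
        from stopnet.preprocessing import preprocess

        stack = preprocess(small_session.recording)
        ns = cnn.NetSpec(temporal=300)
        spec = cnn.TrainSpec(max_epochs=2, batch_size=16, seed=0)
        try:
            nn1, nn2 = train_cascade(stack, small_session.events, [0], spec, ns, seed=0)
        except CascadeDegeneracyError:
            pytest.skip("2-epoch NN1 was degenerate on this fixture")
        test_reps = set(int(r) for r in small_session.events.repetitions_in_trial(1))
        assert not (set(nn1.provenance["reps"]) & test_reps)
        assert not (set(nn2.provenance["reps"]) & test_reps)
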