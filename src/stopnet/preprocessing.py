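"""Causal EEG cleaning and band decomposition, then sliding-epoch labeling.

The chain is strictly causal because the decoder runs in a closed loop:

1. ocular artifacts are removed sample-by-sample with an H-infinity adaptive
   filter using the 4 EOG channels plus a constant drift regressor;
2. four second-order state-variable band-pass filters split the cleaned
   signal into 0.4-3, 2-4, 3-6 and 5-8 Hz bands;
3. 0.6-s epochs are cut at a 0.1-s stride and labeled walk/stop from the
   laser and stop-cue events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EventLog, Recording

BAND_EDGES: list[tuple[float, float]] = [(0.4, 3.0), (2.0, 4.0), (3.0, 6.0), (5.0, 8.0)]

EPOCH_LEN_S = 0.6
EPOCH_STRIDE_S = 0.1
CLASS1_WINDOW_S = (-8.0, 0.2)   # relative to laser onset
CLASS2_PRE_S = -0.2             # class-2 window is [laser-0.2, stop_cue]
OVERLAP_MIN_S = 0.4
NN1_EPOCHS_PER_SIDE = 4         # 4 x 0.1-s strides + 0.6 s = 0.9 s per side

LABEL_UNLABELED, LABEL_WALK, LABEL_STOP = 0, 1, 2


# ---------------------------------------------------------------------------
# H-infinity ocular artifact removal
# ---------------------------------------------------------------------------

@dataclass
class HinfConfig:
    """Parameters of the H-infinity adaptive artifact filter.

    gamma is the robustness bound (>1; smaller = more aggressive adaptation),
    q the adaptation-rate term added to the error covariance each sample, p0
    the initial covariance scale, and ``drift`` toggles the constant
    regressor that absorbs slow drift/offset.  ``settle_s`` marks the initial
    convergence span (the subject stands still for the first 15 s); those
    samples are flagged, not deleted.
    """

    gamma: float = 1.15
    q: float = 1e-10
    p0: float = 0.01
    drift: bool = True
    settle_s: float = 15.0

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.q <= 0 or self.p0 <= 0:
            raise ValueError("q and p0 must be positive")


@dataclass
class HinfResult:
    recording: Recording
    weights: np.ndarray       # (n_eeg, n_ref) final weights
    settle_samples: int       # samples flagged as convergence time


def remove_ocular_artifacts(rec: Recording, config: HinfConfig | None = None) -> HinfResult:
    """Subtract the EOG-correlated (and drift) component from every channel.

    A single gain/covariance recursion is shared across channels because the
    regressor (4 EOG channels + constant) is common to all of them; only the
    weight vectors differ, so the per-sample update is vectorized over the 27
    channels.  The recursion is the rank-1 form of the H-infinity Riccati
    update with a feasibility guard on ``1 - gamma^-2 r'Pr``.
    """
    config = config or HinfConfig()
    if rec.eog.shape[0] != 4:
        raise ValueError(f"H-infinity filtering expects 4 EOG channels, got {rec.eog.shape[0]}")
    n_ch, n = rec.eeg.shape
    n_ref = 4 + (1 if config.drift else 0)

    g2 = 1.0 / config.gamma ** 2
    P = np.eye(n_ref) * config.p0
    W = np.zeros((n_ch, n_ref))
    cleaned = np.empty_like(rec.eeg)
    eog = rec.eog
    eeg = rec.eeg
    for t in range(n):
        r = np.empty(n_ref)
        r[:4] = eog[:, t]
        if config.drift:
            r[4] = 1.0
        e = eeg[:, t] - W @ r          # a-priori (cleaned) output
        cleaned[:, t] = e
        Pr = P @ r
        rPr = float(r @ Pr)
        denom = 1.0 - g2 * rPr
        if denom > 1e-12:              # feasibility guard
            Pt = P + np.outer(Pr, Pr) * (g2 / denom)
            Ptr = Pt @ r
        else:
            Pt, Ptr = P, Pr
        g = Ptr / (1.0 + float(r @ Ptr))
        W += np.outer(e, g)
        c = 1.0 - g2
        P = P - np.outer(Pr, Pr) * (c / (1.0 + c * rPr))
        P[np.diag_indices_from(P)] += config.q

    out = Recording(cleaned, rec.eog.copy(), rec.fs, list(rec.channel_names),
                    list(rec.eog_names), rec.t0)
    return HinfResult(out, W, int(round(config.settle_s * rec.fs)))


# ---------------------------------------------------------------------------
# state-variable band-pass bank
# ---------------------------------------------------------------------------

def design_band_sos(low: float, high: float, fs: float) -> np.ndarray:
    """Second-order band-pass section for one analysis band.

    The analog prototype is the band-pass output of a state-variable filter,
    ``H(s) = Bs / (s^2 + Bs + w0^2)`` with bandwidth ``B`` and center ``w0``
    set by the band edges; discretized by the bilinear transform with
    edge prewarping (equivalently a first-order Butterworth band-pass).
    """
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz is not below Nyquist ({fs / 2} Hz)")
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    return sps.butter(1, [low, high], btype="bandpass", fs=fs, output="sos")


def band_frequency_response(low: float, high: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Analytic magnitude response of the continuous-time prototype."""
    w = 2 * np.pi * np.asarray(freqs_hz, dtype=float)
    B = 2 * np.pi * (high - low)
    w0sq = (2 * np.pi * low) * (2 * np.pi * high)
    h = (1j * w * B) / ((1j * w) ** 2 + 1j * w * B + w0sq)
    return np.abs(h)


@dataclass
class BandStack:
    """Band-decomposed multichannel signal: (n_bands, n_channels, n_samples)."""

    data: np.ndarray
    fs: float
    band_edges: list[tuple[float, float]] = field(default_factory=lambda: list(BAND_EDGES))

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("BandStack data must be 3-D")
        if self.data.shape[0] != len(self.band_edges):
            raise ValueError("band count mismatch")
        for low, high in self.band_edges:
            if not 0 < low < high:
                raise ValueError("band edges must be positive with low < high")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


class BandpassBank:
    """Causal streaming filter bank with persistent per-channel state.

    Filter state carries across successive :meth:`process` calls, so feeding
    a signal in chunks produces exactly the same output as one call (the
    online/pseudo-online equivalence the closed loop requires).
    """

    def __init__(self, n_channels: int, fs: float,
                 band_edges: list[tuple[float, float]] | None = None):
        self.band_edges = list(band_edges or BAND_EDGES)
        self.fs = fs
        self.n_channels = n_channels
        self.sos = [design_band_sos(lo, hi, fs) for lo, hi in self.band_edges]
        self._zi = [
            np.zeros((s.shape[0], n_channels, 2)) for s in self.sos
        ]

    def process(self, chunk: np.ndarray) -> np.ndarray:
        """Filter a (n_channels, n_new_samples) chunk into all bands."""
        if chunk.shape[0] != self.n_channels:
            raise ValueError("channel count changed mid-stream")
        out = np.empty((len(self.sos), chunk.shape[0], chunk.shape[1]))
        for b, s in enumerate(self.sos):
            y, zf = sps.sosfilt(s, chunk, axis=-1, zi=self._zi[b])
            out[b] = y
            self._zi[b] = zf
        return out


def bandpass_bank(rec: Recording, band_edges: list[tuple[float, float]] | None = None) -> BandStack:
    """Apply the four causal band-pass filters to a cleaned recording."""
    bank = BandpassBank(rec.eeg.shape[0], rec.fs, band_edges)
    return BandStack(bank.process(rec.eeg), rec.fs, bank.band_edges)


# ---------------------------------------------------------------------------
# sliding epochs + labeling
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Fixed-length analysis windows over a BandStack, labels attached.

    Epoch tensors are materialized lazily (:meth:`tensor`) because the
    0.1-s stride makes 6x-overlapping copies of long sessions expensive.
    """

    stack: BandStack
    starts: np.ndarray                # sample index of each epoch start
    labels: np.ndarray                # 0 unlabeled / 1 walk / 2 stop
    rep_ids: np.ndarray               # repetition index or -1
    epoch_len: int

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def fs(self) -> float:
        return self.stack.fs

    def start_times_s(self) -> np.ndarray:
        return self.starts / self.fs

    def tensor(self, indices: np.ndarray | None = None, dtype=np.float32) -> np.ndarray:
        """Materialize epochs as (n, n_bands, n_channels, epoch_len)."""
        idx = np.arange(len(self.starts)) if indices is None else np.asarray(indices)
        n_bands, n_ch, _ = self.stack.data.shape
        out = np.empty((len(idx), n_bands, n_ch, self.epoch_len), dtype=dtype)
        for k, i in enumerate(idx):
            s = int(self.starts[i])
            out[k] = self.stack.data[:, :, s : s + self.epoch_len]
        return out

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.stack, self.starts[mask], self.labels[mask],
                        self.rep_ids[mask], self.epoch_len)


def extract_epochs(stack: BandStack, fs: float | None = None) -> EpochSet:
    """Cut the 0.6-s / 0.1-s-stride sliding epochs starting at t = 0.

    The number of epochs is ``floor((T - 0.6) / 0.1) + 1`` (0 when the signal
    is shorter than one epoch).
    """
    fs = fs or stack.fs
    epoch_len = int(round(EPOCH_LEN_S * fs))
    stride = int(round(EPOCH_STRIDE_S * fs))
    n = stack.n_samples
    if n < epoch_len:
        starts = np.empty(0, dtype=np.int64)
    else:
        starts = np.arange(0, n - epoch_len + 1, stride, dtype=np.int64)
    return EpochSet(stack, starts, np.zeros(len(starts), dtype=np.int64),
                    np.full(len(starts), -1, dtype=np.int64), epoch_len)


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_epochs(epochs: EpochSet, events: EventLog, mode: str = "wide") -> EpochSet:
    """Attach walk/stop labels to epochs from the laser and stop-cue events.

    wide mode (NN2 harvesting / pseudo-online ground truth): an epoch is
    class 2 (stop) when >= 0.4 s of it lies in ``[laser - 0.2 s, stop_cue]``,
    else class 1 (walk) when >= 0.4 s lies in ``[laser - 8 s, laser + 0.2 s]``
    of some repetition; an epoch qualifying for both is class 2 (the
    stimulus-locked activity is the detection target).  Epochs touching a
    discard window are left unlabeled.

    nn1_train mode: per repetition, exactly the 4 epochs ending at/before the
    laser (walk) and the 4 starting at/after it (stop) -- the 0.9-s spans on
    each side of the stimulus.
    """
    fs = epochs.fs
    if mode == "nn1_train":
        return _label_nn1_train(epochs, events)
    if mode != "wide":
        raise ValueError(f"unknown labeling mode {mode!r}")

    labels = np.zeros(len(epochs), dtype=np.int64)
    rep_ids = np.full(len(epochs), -1, dtype=np.int64)
    lasers = events.laser_onsets / fs
    stops = np.where(events.stop_cues >= 0, events.stop_cues / fs, np.nan)
    for rep, laser in enumerate(lasers):
        if np.isnan(stops[rep]):
            warnings.warn(
                f"repetition {rep} has no stop cue; it contributes walk epochs only",
                stacklevel=2,
            )
    t0 = epochs.start_times_s()
    t1 = t0 + epochs.epoch_len / fs
    trial_bounds_s = [(s / fs, e / fs) for s, e in events.trial_bounds]
    discard_s = [(s / fs, e / fs) for s, e in events.discard_windows]

    for i in range(len(epochs)):
        a0, a1 = t0[i], t1[i]
        if any(_overlap(a0, a1, d0, d1) > 0 for d0, d1 in discard_s):
            continue
        if not any(b0 <= a0 and a1 <= b1 for b0, b1 in trial_bounds_s):
            continue
        # class 2 first: tie-break in favor of the stimulus-locked class
        assigned = False
        for rep, laser in enumerate(lasers):
            if np.isnan(stops[rep]):
                continue
            if _overlap(a0, a1, laser + CLASS2_PRE_S, stops[rep]) >= OVERLAP_MIN_S - 1e-9:
                labels[i], rep_ids[i], assigned = LABEL_STOP, rep, True
                break
        if assigned:
            continue
        for rep, laser in enumerate(lasers):
            w0, w1 = laser + CLASS1_WINDOW_S[0], laser + CLASS1_WINDOW_S[1]
            if _overlap(a0, a1, w0, w1) >= OVERLAP_MIN_S - 1e-9:
                labels[i], rep_ids[i] = LABEL_WALK, rep
                break
    return EpochSet(epochs.stack, epochs.starts, labels, rep_ids, epochs.epoch_len)


def _label_nn1_train(epochs: EpochSet, events: EventLog) -> EpochSet:
    """Build the laser-locked 4+4 epochs per repetition (0.9 s per side)."""
    fs = epochs.fs
    stride = int(round(EPOCH_STRIDE_S * fs))
    epoch_len = epochs.epoch_len
    span = epoch_len + (NN1_EPOCHS_PER_SIDE - 1) * stride  # 0.9 s in samples
    starts, labels, rep_ids = [], [], []
    n = epochs.stack.n_samples
    for rep, laser in enumerate(events.laser_onsets):
        laser = int(laser)
        trial = events.trial_of(laser)
        lo = events.trial_bounds[trial][0] if trial is not None else 0
        hi = events.trial_bounds[trial][1] if trial is not None else n
        if laser - span < lo or laser + span > hi:
            warnings.warn(
                f"repetition {rep} too close to a trial edge; skipped", stacklevel=2
            )
            continue
        for k in range(NN1_EPOCHS_PER_SIDE):
            starts.append(laser - span + k * stride)   # ends at/before laser
            labels.append(LABEL_WALK)
            rep_ids.append(rep)
        for k in range(NN1_EPOCHS_PER_SIDE):
            starts.append(laser + k * stride)          # starts at/after laser
            labels.append(LABEL_STOP)
            rep_ids.append(rep)
    return EpochSet(
        epochs.stack,
        np.asarray(starts, dtype=np.int64),
        np.asarray(labels, dtype=np.int64),
        np.asarray(rep_ids, dtype=np.int64),
        epoch_len,
    )


def preprocess(rec: Recording, hinf: HinfConfig | None = None) -> BandStack:
    """Full causal chain: H-infinity ocular removal then the band bank."""
    res = remove_ocular_artifacts(rec, hinf)
    return bandpass_bank(res.recording)
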