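"""Synthetic obstacle-stop sessions: protocol timing, EEG, EOG and IMU.

The generator emulates the structure the pipeline needs end-to-end: laser
events laid out per protocol variant (counts are exact by construction), a
stimulus-locked evoked response over centro-parietal channels whose energy
lives in the 0.4-8 Hz analysis bands, 1/f background noise, blink artifacts
mixed from an EOG source, a step-locked gait artifact, and foot IMU traces
whose stop impulses encode the ground-truth stop cues.  It makes no claim
of biophysical realism (no volume conduction, no non-stationarity beyond
the scripted events); it is the controlled test bed for every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import DEFAULT_EEG_CHANNELS, DEFAULT_EOG_CHANNELS, EventLog, ImuTrace, Recording
from .preprocessing import BAND_EDGES, BandpassBank

_PRESETS = {
    # variant: (n_trials, reps_per_trial, laser_gap_s, discard_s)
    "treadmill": (9, 9, (10.0, 12.0), 0.0),
    "exoskeleton": (8, 5, (10.0, 12.0), 4.0),
    "patient": (4, 5, (6.0, 8.0), 4.0),
}


@dataclass
class ProtocolSpec:
    """Session layout.  Presets reproduce the study protocols exactly:
    treadmill 9x9 = 81 repetitions, exoskeleton 8x5 = 40, patient 4x5 = 20."""

    variant: str = "treadmill"
    n_trials: int = 9
    trial_len_s: float = 120.0
    reps_per_trial: int = 9
    laser_gap_s: tuple[float, float] = (10.0, 12.0)
    laser_dur_s: float = 1.0
    post_activation_discard_s: float = 0.0
    stop_latency_s: tuple[float, float] = (1.0, 2.0)
    restart_delay_s: float = 2.0
    intertrial_gap_s: float = 5.0
    lead_in_s: float = 15.0       # initial rest (artifact-filter convergence)
    fs: float = 500.0
    fs_imu: float = 100.0

    @classmethod
    def preset(cls, variant: str, **overrides) -> "ProtocolSpec":
        if variant not in _PRESETS:
            raise ValueError(f"unknown protocol variant {variant!r}")
        n_trials, reps, gap, discard = _PRESETS[variant]
        spec = cls(variant=variant, n_trials=n_trials, reps_per_trial=reps,
                   laser_gap_s=gap, post_activation_discard_s=discard)
        return replace(spec, **overrides) if overrides else spec

    @property
    def n_repetitions(self) -> int:
        return self.n_trials * self.reps_per_trial


@dataclass
class ErpSpec:
    """Stimulus-locked evoked response inserted at each laser onset.

    The template is a positive P3-like cos^2 bump (peak ``latency_s``, width
    ``width_s``) plus a slower windowed deflection at ``slow_freq_hz`` so all
    four analysis bands carry signal; it is identically zero before the
    laser.  ``topography`` maps channel name -> gain (centro-parietal
    emphasis by default); per-repetition amplitude/latency jitter emulates
    single-trial variability.
    """

    latency_s: float = 0.35
    width_s: float = 0.30
    amplitude_uv: float = 8.0
    slow_amplitude_uv: float = 6.0
    slow_freq_hz: float = 1.5
    amp_jitter: float = 0.15
    latency_jitter_s: float = 0.03
    topography: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0 or self.slow_amplitude_uv < 0:
            raise ValueError("amplitudes must be >= 0")


_DEFAULT_TOPOGRAPHY = {
    "Cz": 1.0, "CPz": 1.0, "CP1": 0.9, "CP2": 0.9, "Pz": 0.85,
    "C1": 0.8, "C2": 0.8, "CP3": 0.7, "CP4": 0.7, "C3": 0.6, "C4": 0.6,
    "P3": 0.55, "P4": 0.55, "FCz": 0.5, "FC1": 0.45, "FC2": 0.45,
    "CP5": 0.4, "CP6": 0.4, "PO3": 0.35, "PO4": 0.35,
}


@dataclass
class NoiseSpec:
    """Background and artifact model for the synthetic EEG."""

    pink_exponent: float = 1.0
    pink_scale_uv: float = 5.0        # broadband rms per channel
    eog_blink_rate_hz: float = 0.15
    blink_amplitude_uv: float = 120.0
    eog_noise_uv: float = 5.0
    eog_mix_range: tuple[float, float] = (0.05, 0.2)
    gait_amplitude_uv: float = 3.0
    gait_cadence_hz: float = 1.8
    imu_noise_g: float = 0.03
    step_amplitude_g: float = 0.5
    stop_amplitude_g: float = 2.5

    def __post_init__(self) -> None:
        for name in ("pink_scale_uv", "blink_amplitude_uv", "eog_noise_uv",
                     "gait_amplitude_uv", "imu_noise_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticSession:
    recording: Recording
    events: EventLog
    imu: dict[str, ImuTrace]
    truth: pd.DataFrame
    components: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# event layout
# ---------------------------------------------------------------------------

def generate_events(p: ProtocolSpec, seed: int = 0) -> tuple[EventLog, pd.DataFrame]:
    """Lay out lasers, stop cues, trials and discard windows per protocol.

    Laser count per trial is capped at ``reps_per_trial`` so the protocol's
    printed repetition totals hold deterministically for every seed.
    """
    rng = np.random.default_rng(seed)
    fs = p.fs
    lasers, stops, trials, discards = [], [], [], []
    rows = []
    t = p.lead_in_s
    for trial in range(p.n_trials):
        t_start = t
        t_end = t_start + p.trial_len_s
        trials.append((int(round(t_start * fs)), int(round(t_end * fs))))
        t_laser = t_start + rng.uniform(*p.laser_gap_s)
        for rep in range(p.reps_per_trial):
            stop_lat = rng.uniform(*p.stop_latency_s)
            t_stop = t_laser + stop_lat
            if t_stop + 0.5 > t_end:
                raise ValueError(
                    f"reps_per_trial={p.reps_per_trial} does not fit in a "
                    f"{p.trial_len_s}-s trial with the given gaps"
                )
            lasers.append(int(round(t_laser * fs)))
            stops.append(int(round(t_stop * fs)))
            rows.append({"rep": len(lasers) - 1, "trial": trial,
                         "laser_s": t_laser, "stop_s": t_stop})
            if p.post_activation_discard_s > 0:
                d0 = t_stop + p.restart_delay_s
                d1 = min(d0 + p.post_activation_discard_s, t_end)
                discards.append((int(round(d0 * fs)), int(round(d1 * fs))))
                t_laser = d1 + rng.uniform(*p.laser_gap_s)
            else:
                t_laser = t_laser + p.laser_dur_s + rng.uniform(*p.laser_gap_s)
        t = t_end + p.intertrial_gap_s
    events = EventLog(np.asarray(lasers), np.asarray(stops), trials, discards)
    return events, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_ch: int, n: int,
                exponent: float, rms: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0)  # relative frequency is enough for 1/f
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return x / cur * rms


def _erp_template(fs: float, e: ErpSpec, amp_scale: float, lat_shift: float) -> np.ndarray:
    """One repetition's evoked waveform, starting at laser onset (t = 0)."""
    dur = max(e.latency_s + e.width_s, 1.0 / e.slow_freq_hz) + 0.2
    t = np.arange(int(round(dur * fs))) / fs
    lat = e.latency_s + lat_shift
    bump = np.where(
        np.abs(t - lat) < e.width_s / 2,
        np.cos(np.pi * (t - lat) / e.width_s) ** 2, 0.0,
    ) * e.amplitude_uv
    slow_dur = 1.0 / e.slow_freq_hz
    win = np.where(t < slow_dur, np.sin(np.pi * t / slow_dur) ** 2, 0.0)
    slow = e.slow_amplitude_uv * np.sin(2 * np.pi * e.slow_freq_hz * t) * win
    return (bump + slow) * amp_scale


def _blink_template(fs: float) -> np.ndarray:
    t = np.arange(int(round(0.35 * fs))) / fs
    return np.sin(np.pi * t / 0.35) ** 2


def _walking_mask(events: EventLog, fs: float, restart_delay_s: float, n: int) -> np.ndarray:
    """True where the subject is walking (in-trial, not between stop and restart)."""
    mask = np.zeros(n, dtype=bool)
    for s, e in events.trial_bounds:
        mask[s:e] = True
    for stop in events.stop_cues:
        if stop >= 0:
            mask[int(stop): int(stop + restart_delay_s * fs)] = False
    return mask


def generate_session(p: ProtocolSpec | None = None, erp: ErpSpec | None = None,
                     noise: NoiseSpec | None = None, seed: int = 0,
                     keep_components: bool = True) -> SyntheticSession:
    """Build a full synchronized session (EEG + EOG + 2 foot IMUs + truth).

    Identical seeds give bit-identical sessions.  ``components`` holds the
    clean ERP sum and the total non-ERP part separately (float32) so tests
    can compute exact SNRs.
    """
    p = p or ProtocolSpec.preset("treadmill")
    erp = erp or ErpSpec()
    noise = noise or NoiseSpec()
    events, truth = generate_events(p, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5707]))
    fs = p.fs
    n = events.trial_bounds[-1][1] + int(round(2.0 * fs))

    ch_names = list(DEFAULT_EEG_CHANNELS)
    topo_map = erp.topography if erp.topography is not None else _DEFAULT_TOPOGRAPHY
    topo = np.array([topo_map.get(c, 0.2) for c in ch_names])

    eeg_noise = _pink_noise(rng, len(ch_names), n, noise.pink_exponent,
                            noise.pink_scale_uv)

    # blink source -> EOG channels and (mixed) into EEG
    blink_src = np.zeros(n)
    tmpl = _blink_template(fs)
    t_blink = rng.exponential(1.0 / max(noise.eog_blink_rate_hz, 1e-9))
    while t_blink * fs < n - len(tmpl):
        i = int(t_blink * fs)
        blink_src[i : i + len(tmpl)] += tmpl * rng.uniform(0.7, 1.3)
        t_blink += rng.exponential(1.0 / max(noise.eog_blink_rate_hz, 1e-9))
    blink_src *= noise.blink_amplitude_uv
    eog_coefs = np.array([1.0, 0.9, -0.5, -0.4])
    eog = (np.outer(eog_coefs, blink_src)
           + rng.standard_normal((4, n)) * noise.eog_noise_uv)
    mix = rng.uniform(*noise.eog_mix_range, size=len(ch_names))
    eog_into_eeg = np.outer(mix, blink_src)

    # gait artifact while walking
    walking = _walking_mask(events, fs, p.restart_delay_s, n)
    tt = np.arange(n) / fs
    gait = (np.sin(2 * np.pi * noise.gait_cadence_hz * tt)
            + 0.4 * np.sin(4 * np.pi * noise.gait_cadence_hz * tt)) * walking
    gait_gain = rng.uniform(0.5, 1.0, size=len(ch_names)) * noise.gait_amplitude_uv
    gait_into_eeg = np.outer(gait_gain, gait)

    # stimulus-locked ERP at each laser
    erp_sum = np.zeros((len(ch_names), n))
    rep_jitter = []
    for _, row in truth.iterrows():
        amp = max(0.0, 1.0 + rng.normal(0.0, erp.amp_jitter)) \
            if erp.amp_jitter > 0 else 1.0
        lat = rng.normal(0.0, erp.latency_jitter_s) if erp.latency_jitter_s > 0 else 0.0
        rep_jitter.append((amp, lat))
        w = _erp_template(fs, erp, amp, lat)
        i = int(round(row["laser_s"] * fs))
        w = w[: n - i]
        erp_sum[:, i : i + len(w)] += np.outer(topo, w)

    eeg = eeg_noise + eog_into_eeg + gait_into_eeg + erp_sum
    rec = Recording(eeg, eog, fs, ch_names, list(DEFAULT_EOG_CHANNELS))

    imu = _generate_imu(p, events, truth, noise, rng, n)
    truth = truth.assign(
        erp_amp_scale=[a for a, _ in rep_jitter],
        erp_lat_shift_s=[l for _, l in rep_jitter],
    )
    components = {}
    if keep_components:
        components = {
            "erp": erp_sum.astype(np.float32),
            "noise": (eeg_noise + eog_into_eeg + gait_into_eeg).astype(np.float32),
        }
    return SyntheticSession(rec, events, imu, truth, components)


def _gauss_pulse(fs: float, width_s: float) -> np.ndarray:
    half = int(round(3 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(-0.5 * (t / width_s) ** 2)


def _generate_imu(p: ProtocolSpec, events: EventLog, truth: pd.DataFrame,
                  noise: NoiseSpec, rng: np.random.Generator, n_eeg: int
                  ) -> dict[str, ImuTrace]:
    """Foot traces: alternating step impulses while walking, a strong stop
    deceleration at each repetition's per-foot stop time.  Traces emulate
    gravity-compensated (linear) acceleration in g."""
    fs = p.fs_imu
    n = int(round(n_eeg / p.fs * fs))
    acc = {side: rng.standard_normal((3, n)) * noise.imu_noise_g
           for side in ("left", "right")}

    walking = _walking_mask(events, p.fs, p.restart_delay_s, n_eeg)
    step_pulse = _gauss_pulse(fs, 0.03) * noise.step_amplitude_g
    period = 1.0 / noise.gait_cadence_hz
    for k, side in enumerate(("left", "right")):
        t_step = p.lead_in_s + k * period / 2  # feet alternate
        while t_step * fs < n:
            i_eeg = int(t_step * p.fs)
            if i_eeg < n_eeg and walking[i_eeg]:
                i = int(t_step * fs) - len(step_pulse) // 2
                lo, hi = max(i, 0), min(i + len(step_pulse), n)
                acc[side][2, lo:hi] += step_pulse[lo - i : hi - i]
            t_step += period

    stop_pulse = _gauss_pulse(fs, 0.04) * noise.stop_amplitude_g
    later = []
    for _, row in truth.iterrows():
        t_stop = row["stop_s"]
        lead = t_stop - rng.uniform(0.1, 0.4)
        later_side = "left" if rng.random() < 0.5 else "right"
        early_side = "right" if later_side == "left" else "left"
        for side, t_ev in ((early_side, lead), (later_side, t_stop)):
            i = int(round(t_ev * fs)) - len(stop_pulse) // 2
            lo, hi = max(i, 0), min(i + len(stop_pulse), n)
            acc[side][0, lo:hi] += stop_pulse[lo - i : hi - i] * 0.5
            acc[side][2, lo:hi] += stop_pulse[lo - i : hi - i]
        later.append(later_side)
    truth["later_foot"] = later
    return {side: ImuTrace(acc[side], fs, side) for side in ("left", "right")}


# ---------------------------------------------------------------------------
# SNR reporting
# ---------------------------------------------------------------------------

def snr_report(session: SyntheticSession, window_s: float = 0.8) -> pd.DataFrame:
    """Per-band ERP-power / noise-power table over the post-laser windows.

    Both components are passed through the same analysis filter bank; power
    is averaged over channels and the ``window_s`` seconds after each laser.
    """
    if not session.components:
        raise ValueError("session was generated without components")
    fs = session.recording.fs
    win = int(round(window_s * fs))
    idx = []
    for laser in session.events.laser_onsets:
        idx.append(np.arange(laser, min(laser + win, session.recording.n_samples)))
    idx = np.concatenate(idx)
    rows = []
    for name in ("erp", "noise"):
        x = session.components[name].astype(np.float64)
        bank = BandpassBank(x.shape[0], fs)
        banded = bank.process(x)
        rows.append([float(np.mean(banded[b][:, idx] ** 2))
                     for b in range(len(BAND_EDGES))])
    erp_p, noise_p = rows
    return pd.DataFrame({
        "band_low_hz": [lo for lo, _ in BAND_EDGES],
        "band_high_hz": [hi for _, hi in BAND_EDGES],
        "erp_power": erp_p,
        "noise_power": noise_p,
        "snr": [e / n if n > 0 else np.inf for e, n in zip(erp_p, noise_p)],
    })
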