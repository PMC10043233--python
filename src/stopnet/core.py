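"""Session data model: synchronized EEG/EOG recordings, event logs, IMU traces.

Conventions used throughout the package:

* sample indexing is 0-based and intervals are half-open ``[start, end)``;
* signals are stored in microvolts (EEG/EOG) or g (IMU);
* all event times live on the EEG sample clock unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: 10-10 montage labels of the 27-electrode cap emulated by the synthetic
#: generator.  The acquisition montage exposes more labels than channels in
#: use; which 27 are active is a property of the session manifest, these are
#: only the defaults.
DEFAULT_EEG_CHANNELS = [
    "Fz", "FC5", "FC1", "FCz", "FC2", "FC6",
    "C3", "Cz", "C4",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P3", "Pz", "P4",
    "PO7", "PO3", "PO4", "PO8",
    "FC3", "FC4", "C1", "C2", "CP3", "CP4",
]

DEFAULT_EOG_CHANNELS = ["EOG1", "EOG2", "EOG3", "EOG4"]


class RoleMappingError(ValueError):
    """A channel expected by the EEG/EOG role map is absent from the file."""


class FormatError(ValueError):
    """The on-disk container violates the expectations of the reader."""


@dataclass
class Recording:
    """Synchronized multichannel EEG + EOG block on a single sample clock.

    Parameters
    ----------
    eeg : ndarray, shape (n_eeg_channels, n_samples)
        Scalp channels in microvolts.
    eog : ndarray, shape (n_eog_channels, n_samples)
        Electrooculography reference channels in microvolts.
    fs : float
        Sampling rate in samples/second (500 for paper-conformant sessions).
    channel_names, eog_names : list of str
        Ordered channel labels; must be unique across both groups.
    t0 : float
        Session-relative start time of sample 0, in seconds.
    """

    eeg: np.ndarray
    eog: np.ndarray
    fs: float
    channel_names: list[str]
    eog_names: list[str] = field(default_factory=lambda: list(DEFAULT_EOG_CHANNELS))
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.eog = np.asarray(self.eog, dtype=np.float64)
        if self.eeg.ndim != 2 or self.eog.ndim != 2:
            raise ValueError("eeg and eog must be 2-D (channels x samples)")
        if self.eeg.shape[1] != self.eog.shape[1]:
            raise ValueError(
                f"eeg and eog sample counts differ: {self.eeg.shape[1]} vs {self.eog.shape[1]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        names = list(self.channel_names) + list(self.eog_names)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if len(self.channel_names) != self.eeg.shape[0]:
            raise ValueError("channel_names length does not match eeg rows")
        if len(self.eog_names) != self.eog.shape[0]:
            raise ValueError("eog_names length does not match eog rows")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def is_paper_conformant(self) -> bool:
        """True when the session has the canonical 27 EEG + 4 EOG layout."""
        return self.eeg.shape[0] == 27 and self.eog.shape[0] == 4


def _as_index_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.int64)
    return a.reshape(-1) if a.size else np.empty(0, dtype=np.int64)


@dataclass
class EventLog:
    """Laser onsets, stop cues and structural windows on the EEG sample clock.

    ``stop_cues`` is aligned with ``laser_onsets`` (one entry per repetition);
    a value of ``-1`` marks a repetition whose stop cue is absent.
    """

    laser_onsets: np.ndarray
    stop_cues: np.ndarray
    trial_bounds: list[tuple[int, int]]
    discard_windows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.laser_onsets = _as_index_array(self.laser_onsets)
        self.stop_cues = _as_index_array(self.stop_cues)
        self.trial_bounds = [(int(s), int(e)) for s, e in self.trial_bounds]
        self.discard_windows = [(int(s), int(e)) for s, e in self.discard_windows]
        if len(self.stop_cues) != len(self.laser_onsets):
            raise ValueError("stop_cues must align 1:1 with laser_onsets (-1 = absent)")
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.laser_onsets) <= 0):
            raise ValueError("laser_onsets must be strictly increasing")
        present = self.stop_cues[self.stop_cues >= 0]
        if np.any(np.diff(present) <= 0):
            raise ValueError("stop_cues must be strictly increasing")
        for laser, stop in zip(self.laser_onsets, self.stop_cues):
            if stop >= 0 and stop <= laser:
                raise ValueError(f"stop cue {stop} does not follow its laser {laser}")
        for s, e in self.trial_bounds + self.discard_windows:
            if e <= s:
                raise ValueError(f"window ({s}, {e}) is empty or reversed")
        for laser in self.laser_onsets:
            if not any(s <= laser < e for s, e in self.trial_bounds):
                raise ValueError(f"laser at {laser} lies outside every trial")

    @property
    def n_repetitions(self) -> int:
        return len(self.laser_onsets)

    def trial_of(self, sample: int) -> int | None:
        """Index of the trial containing ``sample``, or None."""
        for k, (s, e) in enumerate(self.trial_bounds):
            if s <= sample < e:
                return k
        return None

    def repetitions_in_trial(self, trial: int) -> np.ndarray:
        """Indices of the repetitions whose laser falls inside ``trial``."""
        s, e = self.trial_bounds[trial]
        return np.where((self.laser_onsets >= s) & (self.laser_onsets < e))[0]


@dataclass
class ImuTrace:
    """Tri-axial accelerometer stream from one foot-worn (or head) IMU."""

    acc: np.ndarray  # (3, n_samples), g
    fs: float
    side: str  # left | right | head

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=np.float64)
        if self.acc.ndim != 2 or self.acc.shape[0] != 3:
            raise ValueError("acc must have shape (3, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.acc)):
            raise ValueError("acc contains non-finite samples")
        if self.side not in ("left", "right", "head"):
            raise ValueError("side must be left, right or head")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]


def resample_index(sample_src: int, fs_src: float, fs_dst: float) -> int:
    """Map a sample index between two clocks sharing the same origin.

    Uses round-half-up so the mapping is deterministic and order-preserving:
    ``round(sample_src * fs_dst / fs_src)``.
    """
    if fs_src <= 0 or fs_dst <= 0:
        raise ValueError("sampling rates must be positive")
    if sample_src < 0:
        raise ValueError("sample index must be non-negative")
    return int(math.floor(sample_src * fs_dst / fs_src + 0.5))
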