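"""Stop-moment labeling from the two foot-worn IMUs.

Per foot, the acceleration modulus is low-pass filtered, rectified, and the
first local maximum above threshold within 2 s of the laser is taken as the
foot's stop; the repetition's stop cue is the later of the two feet mapped
onto the EEG sample clock.  Repetitions where neither foot shows a
qualifying peak are flagged for manual review rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ImuTrace, resample_index

#: acceleration-modulus threshold (g, on the filtered signal) and search span
STOP_THRESHOLD_G = 1.0
SEARCH_WINDOW_S = 2.0
#: causal low-pass applied to the modulus (2nd-order Butterworth).  8 Hz
#: keeps the stop-deceleration envelope while its group delay (~30 ms) stays
#: well inside the 50-ms labeling accuracy the pipeline needs.
LOWPASS_HZ = 8.0


@dataclass
class StopDetection:
    """Outcome of stop labeling for one repetition."""

    per_foot_peak: dict[str, int | None]   # sample index on the IMU clock
    stop_cue: int | None                   # sample index on the EEG clock
    needs_review: bool
    threshold: float = STOP_THRESHOLD_G
    search_window_s: float = SEARCH_WINDOW_S


def preprocess_imu(trace: ImuTrace, lowpass_hz: float = LOWPASS_HZ) -> np.ndarray:
    """|low-pass(||acc||_2)|: the scalar stop-envelope series, same length."""
    if not np.all(np.isfinite(trace.acc)):
        raise ValueError("IMU trace contains non-finite samples")
    modulus = np.linalg.norm(trace.acc, axis=0)
    sos = sps.butter(2, lowpass_hz, btype="low", fs=trace.fs, output="sos")
    return np.abs(sps.sosfilt(sos, modulus))


def _first_peak(series: np.ndarray, start: int, end: int, threshold: float) -> int | None:
    """First strict local maximum above threshold in (start, end]; plateaus
    take their first sample."""
    seg = series[max(start, 1) : min(end + 1, len(series) - 1)]
    if seg.size == 0:
        return None
    offset = max(start, 1)
    prev = series[offset - 1 : offset - 1 + seg.size]
    nxt = series[offset + 1 : offset + 1 + seg.size]
    cand = np.where((seg > threshold) & (seg > prev) & (seg >= nxt))[0]
    for i in cand:
        # plateau rule: first sample of a flat top counts, later ones do not
        if seg[i] > prev[i]:
            return int(i + offset)
    return None


def detect_stop(left: np.ndarray, right: np.ndarray, laser_sample_imu: int,
                fs_imu: float, fs_eeg: float,
                threshold: float = STOP_THRESHOLD_G,
                search_window_s: float = SEARCH_WINDOW_S) -> StopDetection:
    """Locate the stop cue for one repetition from both feet's envelopes.

    ``left``/``right`` are preprocessed envelope series on the IMU clock;
    ``laser_sample_imu`` the laser onset on that clock.  The result's
    ``stop_cue`` is on the EEG clock (``fs_eeg``).
    """
    end = laser_sample_imu + int(round(search_window_s * fs_imu))
    peaks = {
        "left": _first_peak(left, laser_sample_imu + 1, end, threshold),
        "right": _first_peak(right, laser_sample_imu + 1, end, threshold),
    }
    found = [p for p in peaks.values() if p is not None]
    if not found:
        return StopDetection(peaks, None, needs_review=True,
                             threshold=threshold, search_window_s=search_window_s)
    # the later foot defines the actual stop of the body
    stop_imu = max(found)
    stop_eeg = resample_index(stop_imu, fs_imu, fs_eeg)
    return StopDetection(peaks, stop_eeg, needs_review=False,
                         threshold=threshold, search_window_s=search_window_s)


def label_stops(left: ImuTrace, right: ImuTrace, laser_onsets_eeg: np.ndarray,
                fs_eeg: float, threshold: float = STOP_THRESHOLD_G) -> list[StopDetection]:
    """Run the full labeling pass over a session's repetitions."""
    lp = preprocess_imu(left)
    rp = preprocess_imu(right)
    out = []
    for laser in np.asarray(laser_onsets_eeg, dtype=np.int64):
        laser_imu = resample_index(int(laser), fs_eeg, left.fs)
        out.append(detect_stop(lp, rp, laser_imu, left.fs, fs_eeg, threshold))
    return out
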