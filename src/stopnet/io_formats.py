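"""Reading and writing of session containers.

EEG + events travel as a BrainVision triplet (``.vhdr``/``.eeg``/``.vmrk``,
IEEE float32 multiplexed) or as EDF+ with annotations (16-bit, so round-trips
are exact only up to the int16 quantization step).  Readers delegate parsing
to :mod:`mne`; the writers are implemented here.  IMU traces are plain CSV
(``time,acc_x,acc_y,acc_z``) and a session manifest is a small YAML file
naming the parts.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_EOG_CHANNELS,
    EventLog,
    FormatError,
    ImuTrace,
    Recording,
    RoleMappingError,
)

#: event-category -> marker description written into the files.  The map is
#: configurable (session manifests may override it) because marker strings
#: are a property of the acquisition setup, not of the method.
DEFAULT_MARKER_MAP = {
    "laser": "laser",
    "stop": "stop",
    "trial_start": "trial_start",
    "trial_end": "trial_end",
    "discard_start": "discard_start",
    "discard_end": "discard_end",
}


# ---------------------------------------------------------------------------
# event <-> marker conversion
# ---------------------------------------------------------------------------

def _events_to_markers(events: EventLog, marker_map: dict) -> list[tuple[int, str]]:
    """Flatten an EventLog into (sample, description) pairs, sorted by sample."""
    out: list[tuple[int, str]] = []
    for s in events.laser_onsets:
        out.append((int(s), marker_map["laser"]))
    for s in events.stop_cues:
        if s >= 0:
            out.append((int(s), marker_map["stop"]))
    for s, e in events.trial_bounds:
        out.append((s, marker_map["trial_start"]))
        out.append((e, marker_map["trial_end"]))
    for s, e in events.discard_windows:
        out.append((s, marker_map["discard_start"]))
        out.append((e, marker_map["discard_end"]))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _pair_windows(starts: list[int], ends: list[int], what: str) -> list[tuple[int, int]]:
    if len(starts) != len(ends):
        raise FormatError(f"unbalanced {what} start/end markers: {len(starts)} vs {len(ends)}")
    return [(s, e) for s, e in zip(sorted(starts), sorted(ends))]


def _markers_to_events(markers: list[tuple[int, str]], marker_map: dict,
                       n_samples: int) -> EventLog:
    rev = {v: k for k, v in marker_map.items()}
    cats: dict[str, list[int]] = {k: [] for k in DEFAULT_MARKER_MAP}
    for sample, desc in markers:
        # BrainVision descriptions come back through mne as "<type>/<desc>"
        name = desc.split("/")[-1]
        if name in rev:
            cats[rev[name]].append(int(sample))
    lasers = sorted(cats["laser"])
    stops = sorted(cats["stop"])
    # align stop cues 1:1 with lasers: first stop strictly after the laser and
    # before the next one; -1 where absent
    aligned = np.full(len(lasers), -1, dtype=np.int64)
    for i, laser in enumerate(lasers):
        nxt = lasers[i + 1] if i + 1 < len(lasers) else n_samples + 1
        cand = [s for s in stops if laser < s < nxt]
        if cand:
            aligned[i] = cand[0]
    trial_bounds = _pair_windows(cats["trial_start"], cats["trial_end"], "trial")
    discard = _pair_windows(cats["discard_start"], cats["discard_end"], "discard")
    if not trial_bounds:
        trial_bounds = [(0, n_samples)]
    return EventLog(np.asarray(lasers), aligned, trial_bounds, discard)


def _resolve_roles(ch_names: list[str], data_uv: np.ndarray,
                   eeg_channels: list[str] | None,
                   eog_channels: list[str] | None) -> tuple[Recording, list[str]]:
    if eog_channels is None:
        eog_channels = [c for c in DEFAULT_EOG_CHANNELS if c in ch_names]
        if not eog_channels:
            eog_channels = [c for c in ch_names if c.upper().startswith("EOG")]
    if eeg_channels is None:
        eeg_channels = [c for c in ch_names if c not in eog_channels]
    missing = [c for c in list(eeg_channels) + list(eog_channels) if c not in ch_names]
    if missing:
        raise RoleMappingError(
            f"channels required by the role map are absent from the file: {missing}"
        )
    idx = {c: i for i, c in enumerate(ch_names)}
    eeg = data_uv[[idx[c] for c in eeg_channels]]
    eog = data_uv[[idx[c] for c in eog_channels]]
    return eeg, eog, list(eeg_channels), list(eog_channels)


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, events: EventLog, path: str | Path,
                      marker_map: dict | None = None) -> list[Path]:
    """Write a BrainVision triplet (float32 multiplexed) and return the paths."""
    marker_map = {**DEFAULT_MARKER_MAP, **(marker_map or {})}
    base = Path(path)
    if base.suffix == ".vhdr":
        base = base.with_suffix("")
    vhdr, vmrk, eeg_file = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    data = np.vstack([rec.eeg, rec.eog]).astype(np.float32)  # µV
    names = list(rec.channel_names) + list(rec.eog_names)
    n_ch = data.shape[0]
    sampling_interval_us = 1e6 / rec.fs

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Data created by stopnet",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_file.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    data.T.reshape(-1).tofile(eeg_file)  # multiplexed: sample-major

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_file.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101000000000000",
    ]
    for k, (sample, desc) in enumerate(_events_to_markers(events, marker_map), start=2):
        mlines.append(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0")  # 1-based positions
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return [vhdr, vmrk, eeg_file]


def _read_brainvision(path: Path, eeg_channels, eog_channels, marker_map):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    return _raw_to_session(raw, eeg_channels, eog_channels, marker_map)


# ---------------------------------------------------------------------------
# EDF+
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, events: EventLog, path: str | Path,
              marker_map: dict | None = None) -> list[Path]:
    """Write an EDF+C file with an annotations channel.

    Signals are quantized to int16 over each channel's observed physical
    range; the tail of the last 1-s data record is zero-padded, so sessions
    whose length is a whole number of seconds round-trip sample-exactly.
    """
    marker_map = {**DEFAULT_MARKER_MAP, **(marker_map or {})}
    path = Path(path)
    data = np.vstack([rec.eeg, rec.eog])  # µV
    names = list(rec.channel_names) + list(rec.eog_names)
    n_sig = data.shape[0]
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(data.shape[1] / spr)) if data.shape[1] else 1

    # physical scaling per channel
    pmin = data.min(axis=1, initial=0.0)
    pmax = data.max(axis=1, initial=0.0)
    span = np.maximum(pmax - pmin, 1e-6)
    pmin = pmin - 0.001 * span
    pmax = pmax + 0.001 * span
    dmin, dmax = -32768, 32767

    # annotation TALs per record
    markers = _events_to_markers(events, marker_map)
    rec_tals: list[bytes] = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for sample, desc in markers:
            # events at/after the end of the signal go into the last record
            if r * spr <= sample < (r + 1) * spr or (r == n_rec - 1 and sample >= n_rec * spr):
                t = sample / fs
                tal += f"+{t:.6f}\x14{desc}\x14\x00".encode("ascii")
        rec_tals.append(tal)
    ann_bytes = max(16, max(len(t) for t in rec_tals))
    ann_bytes += ann_bytes % 2
    ann_spr = ann_bytes // 2

    header_bytes = 256 * (1 + n_sig + 1)
    now = _dt.datetime(2020, 1, 1)
    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field("X X X X", 80)
    hdr += _edf_field("Startdate 01-JAN-2020 X stopnet X", 80)
    hdr += _edf_field(now.strftime("%d.%m.%y"), 8)
    hdr += _edf_field(now.strftime("%H.%M.%S"), 8)
    hdr += _edf_field(header_bytes, 8)
    hdr += _edf_field("EDF+C", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(1, 8)  # record duration, s
    hdr += _edf_field(n_sig + 1, 4)

    labels = names + ["EDF Annotations"]
    hdr += b"".join(_edf_field(lb, 16) for lb in labels)
    hdr += b"".join(_edf_field("", 80) for _ in labels)  # transducer
    hdr += b"".join(_edf_field("uV", 8) for _ in names) + _edf_field("", 8)
    hdr += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmin) + _edf_field(-1, 8)
    hdr += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmax) + _edf_field(1, 8)
    hdr += b"".join(_edf_field(dmin, 8) for _ in labels)
    hdr += b"".join(_edf_field(dmax, 8) for _ in labels)
    hdr += b"".join(_edf_field("", 80) for _ in labels)  # prefilter
    hdr += b"".join(_edf_field(spr, 8) for _ in names) + _edf_field(ann_spr, 8)
    hdr += b"".join(_edf_field("", 32) for _ in labels)

    # re-read the physical ranges exactly as the ASCII header stores them so
    # the digitization is consistent with what a reader will decode
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (dmax - dmin) / (pmax_r - pmin_r)

    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : data.shape[1]] = data
    dig = np.round((padded - pmin_r[:, None]) * gain[:, None] + dmin).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            f.write(dig[:, r * spr : (r + 1) * spr].tobytes())
            f.write(rec_tals[r].ljust(ann_bytes, b"\x00"))
    return [path]


def _read_edf(path: Path, eeg_channels, eog_channels, marker_map):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _raw_to_session(raw, eeg_channels, eog_channels, marker_map)


def _raw_to_session(raw, eeg_channels, eog_channels, marker_map):
    marker_map = {**DEFAULT_MARKER_MAP, **(marker_map or {})}
    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # mne is SI (volts)
    eeg, eog, eeg_names, eog_names = _resolve_roles(
        raw.ch_names, data_uv, eeg_channels, eog_channels
    )
    rec = Recording(eeg, eog, fs, eeg_names, eog_names)
    markers = [
        (int(round(onset * fs)), desc)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    events = _markers_to_events(markers, marker_map, rec.n_samples)
    return rec, events


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, events: EventLog, path: str | Path,
                    dialect: str = "brainvision", marker_map: dict | None = None) -> list[Path]:
    if dialect == "brainvision":
        return write_brainvision(rec, events, path, marker_map)
    if dialect == "edf":
        return write_edf(rec, events, path, marker_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path: str | Path, dialect: str | None = None,
                   eeg_channels: list[str] | None = None,
                   eog_channels: list[str] | None = None,
                   marker_map: dict | None = None) -> tuple[Recording, EventLog]:
    """Read a session container and split channels into EEG/EOG roles.

    ``eeg_channels``/``eog_channels`` name the channels to use (the role map);
    when omitted, EOG channels are recognized by their ``EOG*`` labels and the
    rest are EEG.  Missing mapped channels raise :class:`RoleMappingError`.
    """
    path = Path(path)
    if dialect is None:
        dialect = {"vhdr": "brainvision", "edf": "edf"}.get(path.suffix.lstrip("."), None)
        if dialect is None:
            raise ValueError(f"cannot infer dialect from {path.name}")
    if dialect == "brainvision":
        return _read_brainvision(path, eeg_channels, eog_channels, marker_map)
    if dialect == "edf":
        return _read_edf(path, eeg_channels, eog_channels, marker_map)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# IMU CSV + session manifest
# ---------------------------------------------------------------------------

def write_imu_csv(trace: ImuTrace, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(trace.n_samples) / trace.fs
    pd.DataFrame(
        {"time": t, "acc_x": trace.acc[0], "acc_y": trace.acc[1], "acc_z": trace.acc[2]}
    ).to_csv(path, index=False)
    return path


def read_imu_csv(path: str | Path, side: str = "left") -> ImuTrace:
    df = pd.read_csv(path)
    for col in ("time", "acc_x", "acc_y", "acc_z"):
        if col not in df.columns:
            raise FormatError(f"IMU CSV is missing column {col!r}")
    dt = np.diff(df["time"].to_numpy())
    if len(dt) and (dt.min() <= 0 or np.ptp(dt) > 1e-6 * dt.mean() + 1e-9):
        raise FormatError("IMU CSV time column is not uniformly increasing")
    fs = 1.0 / dt.mean() if len(dt) else 100.0
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy().T
    return ImuTrace(acc, float(round(fs, 6)), side)


def write_manifest(path: str | Path, eeg_file: str, dialect: str,
                   imu_files: dict[str, str] | None = None,
                   eeg_channels: list[str] | None = None,
                   eog_channels: list[str] | None = None,
                   marker_map: dict | None = None,
                   protocol: str = "treadmill") -> Path:
    doc = {
        "eeg": eeg_file,
        "dialect": dialect,
        "imu": imu_files or {},
        "channels": {"eeg": eeg_channels, "eog": eog_channels},
        "markers": marker_map or dict(DEFAULT_MARKER_MAP),
        "protocol": protocol,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_session(manifest_path: str | Path):
    """Load a full session (Recording, EventLog, {side: ImuTrace}) from YAML."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    root = manifest_path.parent
    rec, events = read_recording(
        root / doc["eeg"],
        dialect=doc.get("dialect"),
        eeg_channels=(doc.get("channels") or {}).get("eeg"),
        eog_channels=(doc.get("channels") or {}).get("eog"),
        marker_map=doc.get("markers"),
    )
    imus = {
        side: read_imu_csv(root / f, side=side)
        for side, f in (doc.get("imu") or {}).items()
    }
    return rec, events, imus
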