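"""Recording and configuration I/O.

Two interchange formats for :class:`~eegharx.simulate.RawRecording`:

* a CSV dialect — first column ``time_s``, one column per channel (µV),
  last column ``activity`` (the annotation label covering that sample, empty
  outside any annotation);
* EDF+C — one signal per channel, 16-bit, with the activity annotations as
  standard EDF+ annotations. The writer is self-contained; reading goes
  through MNE's EDF reader.

Simulation configs round-trip through YAML with the field names of
:class:`~eegharx.simulate.SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ActivityProfile, RawRecording, SimulationConfig


# ---------------------------------------------------------------- CSV dialect

def write_csv(recording: RawRecording, path: str | Path) -> None:
    t = np.arange(recording.n_times) / recording.sampling_rate_hz
    activity = np.full(recording.n_times, "", dtype=object)
    for start, end, label in recording.annotations:
        i0 = int(round(start * recording.sampling_rate_hz))
        i1 = int(round(end * recording.sampling_rate_hz))
        activity[i0:i1] = label
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(recording.channel_labels):
        df[ch] = recording.samples[i]
    df["activity"] = activity
    df.to_csv(path, index=False, float_format="%.6g")


def read_csv(path: str | Path) -> RawRecording:
    df = pd.read_csv(path, keep_default_na=False)
    if df.columns[0] != "time_s" or df.columns[-1] != "activity":
        raise ValueError("expected columns: time_s, <channels...>, activity")
    channels = list(df.columns[1:-1])
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording too short")
    fs = float(round(1.0 / np.median(np.diff(t)), 6))
    samples = df[channels].to_numpy(dtype=float).T
    labels = df["activity"].astype(str).to_numpy()
    annotations = []
    i = 0
    while i < len(labels):
        if labels[i]:
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            annotations.append((i / fs, j / fs, labels[i]))
            i = j
        else:
            i += 1
    return RawRecording(
        channel_labels=channels, sampling_rate_hz=fs,
        samples=samples, annotations=annotations,
    )


# ------------------------------------------------------------------ EDF+ I/O

def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"field {s!r} longer than {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path: str | Path) -> None:
    """Write an EDF+C file: 1-s data records, 16-bit samples, annotations in
    a standard 'EDF Annotations' signal."""
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_times // fs
    if n_records * fs != recording.n_times:
        raise ValueError("EDF writer requires a whole number of 1-s records")

    n_sig = recording.n_channels + 1  # + annotation channel
    data = recording.samples

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_max = np.ceil(phys_max * 1.05 * 100) / 100
    dig_max = 32767

    tals = []
    for start, end, label in recording.annotations:
        tals.append(f"+{start:g}\x15{end - start:g}\x14{label}\x14\x00".encode("ascii"))
    record_tal = [b"" for _ in range(n_records)]
    for start_rec, tal in zip(
        (int(np.floor(s)) for s, _, _ in recording.annotations), tals
    ):
        if 0 <= start_rec < n_records:
            record_tal[start_rec] += tal
    ann_bytes = max(
        (len(f"+{r}\x14\x14\x00".encode()) + len(record_tal[r]) for r in range(n_records)),
        default=16,
    )
    ann_samples = (ann_bytes + 1) // 2 + 8  # headroom, in 2-byte samples

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))  # local patient id (anonymous)
        fh.write(_ascii("Startdate X X X X", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(256 * (n_sig + 1), 8))
        fh.write(_ascii("EDF+C", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))  # record duration, seconds
        fh.write(_ascii(n_sig, 4))

        labels = [
            f"EEG {ch}" if ch not in ("EOG", "EMG") else ch
            for ch in recording.channel_labels
        ] + ["EDF Annotations"]
        for lab in labels:
            fh.write(_ascii(lab, 16))
        for _ in range(n_sig):
            fh.write(_ascii("", 80))  # transducer
        for i in range(n_sig):
            fh.write(_ascii("uV" if i < recording.n_channels else "", 8))
        for i in range(n_sig):
            fh.write(_ascii(f"{-phys_max[i]:.2f}" if i < recording.n_channels else -1, 8))
        for i in range(n_sig):
            fh.write(_ascii(f"{phys_max[i]:.2f}" if i < recording.n_channels else 1, 8))
        for i in range(n_sig):
            fh.write(_ascii(-dig_max if i < recording.n_channels else -32768, 8))
        for _ in range(n_sig):
            fh.write(_ascii(dig_max, 8))
        for _ in range(n_sig):
            fh.write(_ascii("", 80))  # prefiltering
        for i in range(n_sig):
            fh.write(_ascii(fs if i < recording.n_channels else ann_samples, 8))
        for _ in range(n_sig):
            fh.write(_ascii("", 32))  # reserved

        scale = dig_max / phys_max
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            for i in range(recording.n_channels):
                dig = np.clip(np.round(data[i, sl] * scale[i]), -dig_max, dig_max)
                fh.write(dig.astype("<i2").tobytes())
            tal = f"+{rec}\x14\x14\x00".encode("ascii") + record_tal[rec]
            fh.write(tal.ljust(ann_samples * 2, b"\x00"))


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF/EDF+ file through MNE; annotations become activity
    intervals. Data are returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    samples = raw.get_data() * 1e6  # MNE loads EEG in volts
    annotations = [
        (float(on), float(on) + float(dur), str(desc))
        for on, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return RawRecording(
        channel_labels=labels, sampling_rate_hz=float(raw.info["sfreq"]),
        samples=samples, annotations=annotations,
    )


# -------------------------------------------------------------- YAML configs

def save_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "profiles" in d:
        d["profiles"] = [ActivityProfile(**p) for p in d["profiles"]]
    config = SimulationConfig(**d)
    config.validate()
    return config
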