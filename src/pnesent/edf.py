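"""Minimal 16-bit EDF writer and MNE-backed reader.

Recordings are stored as plain EDF (the continuous subset of EDF+): a fixed
256-byte header, one 256-byte header block per signal, then 1-second data
records of little-endian 16-bit integers scaled between each signal's
physical min/max. Reading goes through :func:`mne.io.read_raw_edf`, which
doubles as an independent check of the writer.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .synth import Recording

__all__ = ["write_edf", "read_edf", "write_cohort", "read_cohort"]

_HDR = 256


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | os.PathLike) -> Path:
    """Write one recording as a 16-bit EDF file with 1-s data records.

    Physical min/max are taken per channel from the data (symmetric, padded
    by 1%), which fixes the quantization step at (max-min)/65535.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError(f"unsupported sampling rate {fs}: must be an integer Hz")
    n_ch = len(recording.channels)
    n_rec = recording.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    data = recording.signal[:, : n_rec * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.01
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    hdr = b"".join([
        _field(0, 8),
        _field(f"X X X {recording.subject_id}"[:80], 80),
        _field(f"Startdate X X X X {recording.class_label}"[:80], 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(_HDR * (1 + n_ch), 8),
        _field("", 44),  # reserved; blank = plain EDF
        _field(n_rec, 8),
        _field(1, 8),  # record duration, s
        _field(n_ch, 4),
    ])
    per_sig = b"".join([
        b"".join(_field(ch[:16], 16) for ch in recording.channels),
        b"".join(_field("", 80) for _ in range(n_ch)),  # transducer
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{phys_min[c]:.6g}"[:8], 8) for c in range(n_ch)),
        b"".join(_field(f"{phys_max[c]:.6g}"[:8], 8) for c in range(n_ch)),
        b"".join(_field(dig_min, 8) for _ in range(n_ch)),
        b"".join(_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),  # prefiltering
        b"".join(_field(spr, 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),  # reserved
    ])

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    dig = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(per_sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(
    path: str | os.PathLike,
    subject_id: str | None = None,
    class_label: str = "",
    require_channels: tuple[str, ...] | None = ("ECG+", "ECG-"),
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV).

    ``require_channels`` names channels that must be present (the pipeline
    needs both ECG leads by default); pass None to disable the check.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = list(raw.ch_names)
    if require_channels:
        for ch in require_channels:
            if ch not in channels:
                raise ValueError(f"EDF file {path.name} is missing channel {ch!r}")
    # MNE scales recognised channel types to SI units (V); recover µV.
    data = raw.get_data() * 1e6
    return Recording(
        subject_id=subject_id or path.stem,
        class_label=class_label,
        fs=float(raw.info["sfreq"]),
        channels=channels,
        signal=data,
    )


def write_cohort(recordings: list[Recording], directory: str | os.PathLike) -> Path:
    """Write one EDF per subject plus a labels.tsv sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["subject_id\tclass_label"]
    for rec in recordings:
        write_edf(rec, directory / f"{rec.subject_id}.edf")
        lines.append(f"{rec.subject_id}\t{rec.class_label}")
    (directory / "labels.tsv").write_text("\n".join(lines) + "\n")
    return directory


def read_cohort(directory: str | os.PathLike) -> list[Recording]:
    directory = Path(directory)
    labels_path = directory / "labels.tsv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.tsv in {directory}")
    labels = dict(
        line.split("\t")
        for line in labels_path.read_text().strip().splitlines()[1:]
    )
    return [
        read_edf(directory / f"{sid}.edf", subject_id=sid, class_label=lab)
        for sid, lab in labels.items()
    ]
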