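"""Signal conditioning: raw recording -> banded, artifact-screened epochs.

The chain is: resample to 256 Hz and keep the common electrodes; broad-band
(0.5-40 Hz) zero-phase FIR filter on the EEG; derive one clean ECG channel
from the two leads (lead difference, Bessel IIR 0.25-40 Hz band-pass, 0.05 Hz
baseline-wander high-pass); segment into non-overlapping 10-s epochs; reject
flat/noisy epochs; per-subject baseline correction; and finally decompose the
EEG into the classic frequency bands while the same ECG channel rides along
with every band.

All FIR filters are linear-phase Hamming designs applied as a single forward
pass with exact integer group-delay compensation on a reflection-padded
signal (equivalent to zero-phase for a symmetric FIR). The Bessel IIR is
applied forward-backward, trading its phase linearity for zero phase so the
ECG stays time-aligned with the EEG bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .synth import EEG_CHANNELS, Recording

__all__ = [
    "BANDS",
    "BandDefinition",
    "EpochSet",
    "resample_to_256",
    "bandpass_eeg",
    "derive_and_filter_ecg",
    "prepare_recording",
    "epoch_signal",
    "reject_artifacts",
    "baseline_correct",
    "decompose_bands",
    "preprocess_cohort",
]

TARGET_FS = 256.0
ECG_NAME = "ECG"


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


#: The analysis bands (Hz).
BANDS = {
    "broad": BandDefinition("broad", 0.5, 40.0),
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 40.0),
}


@dataclass
class EpochSet:
    """Epoch x channel x sample tensor with per-epoch subject/class tags."""

    data: np.ndarray
    fs: float
    channels: list[str]
    subject_ids: np.ndarray
    class_labels: np.ndarray
    band: str = "broad"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.class_labels = np.asarray(self.class_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (epoch, channel, sample)")
        if self.data.shape[0] != self.subject_ids.size != self.class_labels.size:
            raise ValueError("per-epoch tags must match epoch count")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis must match channel list")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def concat(self, other: "EpochSet") -> "EpochSet":
        if self.channels != other.channels or self.fs != other.fs:
            raise ValueError("incompatible EpochSets")
        return replace(
            self,
            data=np.concatenate([self.data, other.data]),
            subject_ids=np.concatenate([self.subject_ids, other.subject_ids]),
            class_labels=np.concatenate([self.class_labels, other.class_labels]),
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _fir_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    """Linear-phase Hamming band-pass; transition = max(0.25*low, 1 Hz)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"cutoffs ({low}, {high}) outside (0, fs/2)")
    trans = max(0.25 * low, 1.0)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd -> integer group delay
    return signal.firwin(
        numtaps, [low, high], pass_zero=False, window="hamming", fs=fs
    )


def _apply_fir_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Single forward pass of a symmetric FIR with group-delay removal.

    Reflection padding of half the filter length on each side keeps edges
    usable; for a linear-phase FIR this equals a zero-phase filter.
    """
    delay = (taps.size - 1) // 2
    x = np.atleast_2d(x)
    pad = min(delay, x.shape[-1] - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    y = signal.fftconvolve(xp, taps[None, :], mode="full", axes=-1)
    start = pad + delay
    return np.squeeze(y[..., start : start + x.shape[-1]])


def bandpass_filter(x: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    """Zero-phase FIR band-pass of one or more channels (last axis = time)."""
    return _apply_fir_zero_phase(np.asarray(x, dtype=float), _fir_bandpass(low, high, fs))


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def resample_to_256(recording: Recording) -> Recording:
    """Downsample to 256 Hz (anti-aliased) and keep the common electrodes."""
    if recording.fs not in (256.0, 512.0, 1024.0):
        raise ValueError(
            f"unsupported sampling rate {recording.fs}: expected 256/512/1024 Hz"
        )
    wanted = list(EEG_CHANNELS) + ["ECG+", "ECG-"]
    for ch in wanted:
        if ch not in recording.channels:
            raise ValueError(f"recording is missing common electrode {ch!r}")
    idx = [recording.channels.index(ch) for ch in wanted]
    sig = recording.signal[idx]
    if recording.fs != TARGET_FS:
        factor = int(recording.fs // TARGET_FS)
        sig = signal.resample_poly(sig, up=1, down=factor, axis=-1)
    return replace_signal(recording, sig, wanted, TARGET_FS)


def replace_signal(rec: Recording, sig, channels, fs) -> Recording:
    return Recording(
        subject_id=rec.subject_id,
        class_label=rec.class_label,
        fs=fs,
        channels=list(channels),
        signal=sig,
    )


def bandpass_eeg(recording: Recording, low: float = 0.5, high: float = 40.0) -> Recording:
    """Broad-band zero-phase FIR on the EEG channels; ECG leads untouched."""
    if recording.fs != TARGET_FS:
        raise ValueError("bandpass_eeg expects a 256 Hz recording")
    sig = recording.signal.copy()
    eeg_idx = [i for i, ch in enumerate(recording.channels)
               if ch not in ("ECG+", "ECG-")]
    sig[eeg_idx] = bandpass_filter(sig[eeg_idx], low, high, recording.fs)
    return replace_signal(recording, sig, recording.channels, recording.fs)


def derive_and_filter_ecg(recording: Recording) -> np.ndarray:
    """(ECG+) - (ECG-), Bessel IIR 0.25-40 Hz, then 0.05 Hz wander removal.

    The Bessel stages are applied forward-backward (zero phase).
    """
    for ch in ("ECG+", "ECG-"):
        if ch not in recording.channels:
            raise ValueError(f"recording is missing ECG lead {ch!r}")
    ecg = recording.channel("ECG+") - recording.channel("ECG-")
    fs = recording.fs
    # order 6: the slow Bessel roll-off needs it to suppress mains-range
    # tones (>20 dB at 60 Hz) while keeping QRS-band droop under 10%
    sos_bp = signal.bessel(6, [0.25, 40.0], btype="bandpass", fs=fs, output="sos")
    # generous padding: the 0.25/0.05 Hz poles ring for seconds and the
    # default pad leaves visible edge transients
    padlen = min(ecg.size - 1, int(10 * fs))
    ecg = signal.sosfiltfilt(sos_bp, ecg, padlen=padlen)
    sos_hp = signal.bessel(2, 0.05, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos_hp, ecg, padlen=padlen)


def prepare_recording(recording: Recording) -> Recording:
    """resample -> broad-band EEG filter -> ECG derivation; 21 channels out."""
    rec = resample_to_256(recording)
    rec = bandpass_eeg(rec)
    ecg = derive_and_filter_ecg(rec)
    eeg_idx = [i for i, ch in enumerate(rec.channels) if ch not in ("ECG+", "ECG-")]
    sig = np.vstack([rec.signal[eeg_idx], ecg[None, :]])
    names = [rec.channels[i] for i in eeg_idx] + [ECG_NAME]
    return replace_signal(rec, sig, names, rec.fs)


def epoch_signal(recording: Recording, epoch_len: float = 10.0) -> EpochSet:
    """Non-overlapping epochs of ``epoch_len`` s; trailing partial dropped."""
    n_per = int(round(epoch_len * recording.fs))
    n_ep = recording.n_samples // n_per
    if n_ep == 0:
        raise ValueError(
            f"recording ({recording.n_samples / recording.fs:.1f} s) shorter "
            f"than one {epoch_len:.0f}-s epoch"
        )
    data = recording.signal[:, : n_ep * n_per]
    data = data.reshape(len(recording.channels), n_ep, n_per).transpose(1, 0, 2)
    return EpochSet(
        data=data,
        fs=recording.fs,
        channels=list(recording.channels),
        subject_ids=np.repeat(recording.subject_id, n_ep),
        class_labels=np.repeat(recording.class_label, n_ep),
        band="broad",
    )


def reject_artifacts(
    epochs: EpochSet,
    flat_uV: float = 1.0,
    ptp_uV: float = 300.0,
    ecg_flat: float = 1e-3,
) -> tuple[EpochSet, pd.DataFrame]:
    """Amplitude-criterion epoch rejection with a reason log.

    Removes (a) flat epochs — every EEG channel's peak-to-peak below
    ``flat_uV``; (b) noisy epochs — any EEG channel's peak-to-peak above
    ``ptp_uV`` (a simple stand-in for consensus-threshold rejectors); and
    (c) flat-ECG epochs (derived ECG peak-to-peak below ``ecg_flat``).
    """
    if flat_uV <= 0 or ptp_uV <= 0 or ecg_flat <= 0:
        raise ValueError("rejection thresholds must be positive")
    eeg_idx = [i for i, ch in enumerate(epochs.channels) if ch != ECG_NAME]
    ptp = np.ptp(epochs.data[:, eeg_idx, :], axis=2)  # epoch x channel
    flat = (ptp < flat_uV).all(axis=1)
    noisy = (ptp > ptp_uV).any(axis=1)
    records = []
    ecg_flat_mask = np.zeros(epochs.n_epochs, dtype=bool)
    if ECG_NAME in epochs.channels:
        ecg_ptp = np.ptp(epochs.data[:, epochs.channels.index(ECG_NAME), :], axis=1)
        ecg_flat_mask = ecg_ptp < ecg_flat
    for i in range(epochs.n_epochs):
        if flat[i]:
            records.append((i, "flat"))
        elif noisy[i]:
            records.append((i, "noisy"))
        elif ecg_flat_mask[i]:
            records.append((i, "flat-ecg"))
    log = pd.DataFrame(records, columns=["epoch", "reason"])
    keep = ~(flat | noisy | ecg_flat_mask)
    kept = EpochSet(
        data=epochs.data[keep],
        fs=epochs.fs,
        channels=epochs.channels,
        subject_ids=epochs.subject_ids[keep],
        class_labels=epochs.class_labels[keep],
        band=epochs.band,
    )
    return kept, log


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each subject's per-channel mean across all retained epochs."""
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to baseline-correct")
    data = epochs.data.copy()
    for sid in np.unique(epochs.subject_ids):
        m = epochs.subject_ids == sid
        mean = data[m].mean(axis=(0, 2), keepdims=True)  # per channel
        data[m] -= mean
    return replace(epochs, data=data)


def decompose_bands(
    epochs: EpochSet, bands: dict[str, BandDefinition] | None = None
) -> dict[str, EpochSet]:
    """Band-pass the EEG channels per band; ECG attached unmodified to each.

    The broad band is the identity pass-through of the input epochs.
    """
    bands = bands or BANDS
    eeg_idx = [i for i, ch in enumerate(epochs.channels) if ch != ECG_NAME]
    out: dict[str, EpochSet] = {}
    for name, bd in bands.items():
        if name == "broad":
            out[name] = replace(epochs, data=epochs.data.copy(), band="broad")
            continue
        data = epochs.data.copy()
        n_ep, _, n_s = data.shape
        eeg = data[:, eeg_idx, :].reshape(n_ep * len(eeg_idx), n_s)
        eeg = bandpass_filter(eeg, bd.low, bd.high, epochs.fs)
        data[:, eeg_idx, :] = eeg.reshape(n_ep, len(eeg_idx), n_s)
        out[name] = replace(epochs, data=data, band=name)
    return out


def preprocess_cohort(
    recordings: list[Recording],
    epoch_len: float = 10.0,
    flat_uV: float = 1.0,
    ptp_uV: float = 300.0,
    bands: dict[str, BandDefinition] | None = None,
) -> tuple[dict[str, EpochSet], pd.DataFrame]:
    """Full chain over a cohort: banded EpochSets plus the rejection log."""
    combined: EpochSet | None = None
    logs = []
    for rec in recordings:
        prepared = prepare_recording(rec)
        epochs = epoch_signal(prepared, epoch_len)
        kept, log = reject_artifacts(epochs, flat_uV=flat_uV, ptp_uV=ptp_uV)
        log.insert(0, "subject_id", rec.subject_id)
        logs.append(log)
        combined = kept if combined is None else combined.concat(kept)
    if combined is None or combined.n_epochs == 0:
        raise ValueError("no epochs survived preprocessing")
    corrected = baseline_correct(combined)
    return decompose_bands(corrected, bands), pd.concat(logs, ignore_index=True)
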