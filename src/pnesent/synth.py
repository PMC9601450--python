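"""Synthetic EEG/ECG cohort generator.

The clinical recordings behind this analysis cannot be redistributed, so the
pipeline is exercised on a generated cohort that carries the statistical
structure the analysis assumes: two classes whose EEG differs in temporal
complexity (1/f spectral exponent, optional AR structure) and in
band-specific oscillatory content, plus a two-lead ECG whose beat-to-beat
(RR) variability differs by class. None of the generator parameters are
claims about PNES or epilepsy physiology — they are configuration.

Per subject, each EEG channel is a mixture of

* background 1/f^beta noise with a class-specific exponent,
* band-limited oscillations (one per classic EEG band) whose amplitude
  differs between classes only in the configured ``informative_bands``,
* a shared 1/f source mixed across channels (spatial correlation), and
* optionally an AR(1) component with class-specific coefficient.

ECG+ / ECG- carry ± half of a quasi-periodic Gaussian-bump QRS beat train
whose RR intervals are jittered with class-specific SD, so the derived lead
difference reconstructs the beat train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EEG_CHANNELS",
    "RAW_CHANNELS",
    "EffectConfig",
    "HRVParams",
    "CohortConfig",
    "Recording",
    "generate_cohort",
    "generate_recording",
    "generate_synthetic_ecg",
    "pink_noise",
]

#: The 20 common scalp electrodes (10-20 montage) plus the two ECG leads.
EEG_CHANNELS = (
    "Fp1", "F7", "T3", "T5", "O1", "F3", "C3", "P3", "Fz", "Cz",
    "Fp2", "F8", "T4", "T6", "O2", "F4", "C4", "P4", "Fpz", "Pz",
)
RAW_CHANNELS = EEG_CHANNELS + ("ECG+", "ECG-")

#: Centre frequency (Hz) of the oscillation injected for each band.
OSC_FREQS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 35.0}

CLASSES = ("PNES", "epilepsy")


@dataclass(frozen=True)
class EffectConfig:
    """Class-contrast parameters.

    ``osc_amp_ratio`` multiplies the oscillation amplitude of the epilepsy
    class in each informative band (1.0 = no contrast). ``beta`` are the 1/f
    spectral exponents per class; ``ar_phi`` optional AR(1) coefficients
    (0 disables the component). ``scale(c)`` returns a copy with every
    contrast scaled towards/away from the no-effect point by factor c —
    used by monotonicity checks.
    """

    osc_amp_ratio: float = 3.0
    beta_pnes: float = 1.0
    beta_epilepsy: float = 1.0
    ar_phi_pnes: float = 0.0
    ar_phi_epilepsy: float = 0.0

    def scale(self, c: float) -> "EffectConfig":
        return EffectConfig(
            osc_amp_ratio=1.0 + c * (self.osc_amp_ratio - 1.0),
            beta_pnes=self.beta_pnes,
            beta_epilepsy=self.beta_pnes + c * (self.beta_epilepsy - self.beta_pnes),
            ar_phi_pnes=self.ar_phi_pnes,
            ar_phi_epilepsy=self.ar_phi_pnes
            + c * (self.ar_phi_epilepsy - self.ar_phi_pnes),
        )

    @classmethod
    def null(cls) -> "EffectConfig":
        """No class contrast at all (downstream accuracy should be chance)."""
        return cls(osc_amp_ratio=1.0, beta_pnes=1.0, beta_epilepsy=1.0,
                   ar_phi_pnes=0.0, ar_phi_epilepsy=0.0)


@dataclass(frozen=True)
class HRVParams:
    """Per-class heart rhythm: mean RR interval (s) and RR jitter SD (s).

    Defaults give both classes a ~70 bpm rhythm with lower beat-to-beat
    variability in the PNES-like class, mirroring reports of reduced
    interictal heart-rate complexity in functional seizures.
    """

    mean_rr_pnes: float = 0.85
    mean_rr_epilepsy: float = 0.85
    jitter_pnes: float = 0.015
    jitter_epilepsy: float = 0.05


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration for the synthetic cohort.

    Defaults mirror the cohort the analysis is designed for: 48 PNES-like
    and 29 epilepsy-like subjects, 10-s epochs at 256 Hz (N = 2560), the 20
    common 10-20 electrodes plus two ECG leads, and a single informative
    band (theta) carrying the class contrast.
    """

    n_pnes: int = 48
    n_epilepsy: int = 29
    epochs_per_subject: int = 20
    fs: float = 256.0
    epoch_len: float = 10.0
    channels: tuple[str, ...] = RAW_CHANNELS
    effect: EffectConfig = field(default_factory=EffectConfig)
    informative_bands: frozenset[str] = frozenset({"theta"})
    hrv: HRVParams = field(default_factory=HRVParams)
    osc_base_amp: float = 5.0  # µV, PNES-class oscillation amplitude
    background_sd: float = 10.0  # µV, 1/f background SD
    shared_source_sd: float = 4.0  # µV, cross-channel common source
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pnes <= 0 or self.n_epilepsy <= 0 or self.epochs_per_subject <= 0:
            raise ValueError("subject and epoch counts must be positive")
        if self.fs <= 2 * 40.0:
            raise ValueError(
                f"fs={self.fs} Hz violates the Nyquist requirement for the "
                "40 Hz analysis band (need fs > 80 Hz)"
            )
        if "ECG+" not in self.channels or "ECG-" not in self.channels:
            raise ValueError("channel list must contain both ECG+ and ECG-")
        unknown = self.informative_bands - set(OSC_FREQS)
        if unknown:
            raise ValueError(f"unknown informative bands: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        """Analysis window length N (2560 at defaults)."""
        return int(round(self.epoch_len * self.fs))

    def with_null_contrast(self) -> "CohortConfig":
        """Copy with zero class contrast everywhere (EEG effect and HRV)."""
        from dataclasses import replace

        jitter = 0.5 * (self.hrv.jitter_pnes + self.hrv.jitter_epilepsy)
        rr = 0.5 * (self.hrv.mean_rr_pnes + self.hrv.mean_rr_epilepsy)
        return replace(
            self,
            effect=EffectConfig.null(),
            hrv=HRVParams(mean_rr_pnes=rr, mean_rr_epilepsy=rr,
                          jitter_pnes=jitter, jitter_epilepsy=jitter),
        )


@dataclass
class Recording:
    """One subject's continuous multichannel signal with its class label.

    EEG channels are in µV; raw ECG leads are in mV-scale arbitrary units.
    """

    subject_id: str
    class_label: str
    fs: float
    channels: list[str]
    signal: np.ndarray  # channels x samples

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != len(self.channels):
            raise ValueError("signal rows must match channel list")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.signal[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


def pink_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f^beta noise via spectral shaping of white Gaussian noise.

    Normalisation uses the analytic SD of the shaped process (Parseval), not
    the realised SD of the draw: realised-SD scaling would couple all epochs
    cut from one recording and imprint a subject-level fingerprint that
    epoch-wise cross-validation could exploit even with zero class contrast.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; it is centred out below
    gain = f ** (-beta / 2.0)
    spec *= gain
    x = np.fft.irfft(spec, n)
    # E[var] = sum(h^2) for the equivalent FIR h with rfft magnitude `gain`
    g2 = gain**2
    expected_var = (g2[0] + 2.0 * g2[1:-1].sum() + g2[-1]) / n if n % 2 == 0 \
        else (g2[0] + 2.0 * g2[1:].sum()) / n
    x -= x.mean()
    return x / np.sqrt(expected_var)


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    x -= x.mean()
    return x * np.sqrt(1.0 - phi**2)  # analytic stationary SD


def generate_synthetic_ecg(
    duration: float,
    fs: float,
    mean_rr: float,
    rr_jitter: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Quasi-periodic Gaussian-bump QRS beat train.

    Beats are placed at cumulative RR intervals drawn as
    ``mean_rr + N(0, rr_jitter)``; each beat is a narrow Gaussian bump
    (sigma = 15 ms) of unit amplitude. With ``rr_jitter = 0`` the train is
    strictly periodic.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if rr_jitter < 0:
        raise ValueError("rr_jitter must be nonnegative")
    if duration < mean_rr:
        raise ValueError("duration shorter than one beat interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    beat_t = mean_rr / 2.0
    sigma = 0.015
    while beat_t < duration:
        x += np.exp(-0.5 * ((t - beat_t) / sigma) ** 2)
        rr = mean_rr + (rng.normal(0.0, rr_jitter) if rr_jitter > 0 else 0.0)
        beat_t += max(rr, 0.2)  # refractory floor
    return x


def generate_recording(
    config: CohortConfig,
    subject_id: str,
    class_label: str,
    rng: np.random.Generator,
) -> Recording:
    """One subject's continuous recording under the configured contrast."""
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}")
    eff = config.effect
    is_epi = class_label == "epilepsy"
    beta = eff.beta_epilepsy if is_epi else eff.beta_pnes
    phi = eff.ar_phi_epilepsy if is_epi else eff.ar_phi_pnes
    duration = config.epochs_per_subject * config.epoch_len
    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs

    eeg_names = [c for c in config.channels if c not in ("ECG+", "ECG-")]
    # fixed montage-determined mixing profile: volume-conduction geometry is
    # a property of the electrode layout, common to all subjects
    mix = 0.5 + 0.5 * np.abs(np.sin(1.0 + np.arange(len(eeg_names))))

    # EEG epochs are drawn as independent segments — emulating rest epochs
    # clipped at scattered times from a long monitoring session rather than
    # one continuous trace. This keeps same-subject epochs exchangeable, so
    # a zero-contrast cohort classifies at chance even under epoch-wise CV.
    n_ep = int(round(duration / config.epoch_len))
    n_per = int(round(config.epoch_len * config.fs))
    t_ep = np.arange(n_per) / config.fs
    sig = np.zeros((len(config.channels), n))
    for e in range(n_ep):
        sl = slice(e * n_per, (e + 1) * n_per)
        shared = pink_noise(n_per, beta, rng) * config.shared_source_sd
        osc = np.zeros(n_per)
        for band, f0 in OSC_FREQS.items():
            amp = config.osc_base_amp
            if band in config.informative_bands and is_epi:
                amp *= eff.osc_amp_ratio
            phase = rng.uniform(0, 2 * np.pi)
            # mild amplitude modulation so oscillations are not pure tones
            am = 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t_ep
                                    + rng.uniform(0, 2 * np.pi))
            osc += amp * am * np.sin(2 * np.pi * f0 * t_ep + phase)
        ei = 0
        for ci, name in enumerate(config.channels):
            if name in ("ECG+", "ECG-"):
                continue
            bg = pink_noise(n_per, beta, rng) * config.background_sd
            ch = bg + mix[ei] * shared + osc
            if phi != 0.0:
                ch = ch + config.background_sd * _ar1(n_per, phi, rng)
            sig[ci, sl] = ch
            ei += 1

    hrv = config.hrv
    mean_rr = hrv.mean_rr_epilepsy if is_epi else hrv.mean_rr_pnes
    jitter = hrv.jitter_epilepsy if is_epi else hrv.jitter_pnes
    ecg = generate_synthetic_ecg(duration, config.fs, mean_rr, jitter, rng)
    ecg = ecg + 0.02 * rng.standard_normal(n)  # electrode noise
    for ci, name in enumerate(config.channels):
        if name == "ECG+":
            sig[ci] = 0.5 * ecg
        elif name == "ECG-":
            sig[ci] = -0.5 * ecg

    return Recording(
        subject_id=subject_id,
        class_label=class_label,
        fs=config.fs,
        channels=list(config.channels),
        signal=sig,
    )


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate the full labelled cohort, deterministic under ``config.seed``.

    Each subject draws from an independent child stream of the cohort seed,
    so per-subject signals do not depend on cohort size or ordering.
    """
    recs: list[Recording] = []
    counts = {"PNES": config.n_pnes, "epilepsy": config.n_epilepsy}
    for class_idx, (label, n_subj) in enumerate(counts.items()):
        for s in range(n_subj):
            ss = np.random.SeedSequence([config.seed, class_idx, s])
            rng = np.random.default_rng(ss)
            recs.append(
                generate_recording(config, f"{label.lower()}_{s:03d}", label, rng)
            )
    return recs
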