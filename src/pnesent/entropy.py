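"""Entropy estimators for banded EEG/ECG epochs.

Six estimators are provided, each computed per channel per 10-s epoch:

* :func:`approximate_entropy` / :func:`sample_entropy` — template-matching
  regularity statistics with run length ``m`` and tolerance ``r`` (Chebyshev
  distance). ApEn includes self-matches; SampEn excludes them.
* :func:`spectral_entropy` — Shannon entropy of the Welch power spectrum,
  normalised by ``ln Ω`` so the white-noise limit is 1.
* :func:`svd_entropy` — Shannon entropy of the normalised squared singular
  values of a delay-embedding (Hankel-structured) matrix, normalised to [0, 1].
* :func:`renyi_entropy` — order-α Rényi entropy (base-2 log) of the amplitude
  histogram of the series; α = 2 by default.
* :func:`wavelet_entropy` — Shannon entropy (natural log) of relative Morlet
  wavelet-level energies.

:func:`extract_features` assembles a :class:`FeatureMatrix` of one value per
(epoch, channel) for a chosen measure, with band-group annotations used by the
grouped permutation importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal

__all__ = [
    "EntropyParams",
    "FeatureMatrix",
    "approximate_entropy",
    "sample_entropy",
    "apen_sampen_grid",
    "spectral_entropy",
    "spectral_entropy_from_psd",
    "svd_entropy",
    "renyi_entropy",
    "renyi_entropy_from_probs",
    "wavelet_entropy",
    "wavelet_entropy_from_energies",
    "morlet_level_energies",
    "extract_features",
    "MEASURES",
]


@dataclass(frozen=True)
class EntropyParams:
    """All estimator parameters in one place.

    m, r_sd parameterise ApEn/SampEn; the tolerance passed to the estimators
    is ``r = r_sd * SD(x)`` computed per epoch per channel. Defaults for m and
    r_sd are the pairs the grid-search protocol selects when it is skipped
    (m=2, r_sd=0.2 for ApEn; m=1, r_sd=0.15 for SampEn).
    """

    apen_m: int = 2
    apen_r_sd: float = 0.2
    sampen_m: int = 1
    sampen_r_sd: float = 0.15
    alpha: float = 2.0
    n_hist_bins: int = 100
    svd_emb: int = 10
    svd_tau: int = 2
    welch_seg_s: float = 1.0
    welch_overlap: float = 0.5
    wavelet_n_scales: int = 10
    wavelet_fmin: float = 0.5
    wavelet_fmax: float = 40.0

    def __post_init__(self) -> None:
        for m in (self.apen_m, self.sampen_m):
            if m not in (1, 2):
                raise ValueError(f"run length m must be 1 or 2, got {m}")
        if not (self.alpha >= 0 and self.alpha != 1):
            raise ValueError("Renyi order alpha must be >= 0 and != 1")
        if self.svd_emb < 2:
            raise ValueError("svd_emb must be >= 2")
        if self.wavelet_n_scales < 2:
            raise ValueError("wavelet_n_scales must be >= 2")


@dataclass
class FeatureMatrix:
    """Epochs x features entropy matrix with band-group annotations.

    ``groups`` maps each column to its band name, which is what the grouped
    permutation importance shuffles jointly. Per single band there are 21
    columns (20 scalp channels + the derived ECG); the combined set
    concatenates the per-band blocks column-wise.
    """

    X: np.ndarray
    feature_names: list[str]
    groups: np.ndarray  # per-column band name
    labels: np.ndarray  # per-epoch class label
    subject_ids: np.ndarray
    measure: str
    params: EntropyParams = field(default_factory=EntropyParams)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            ep, col = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite feature at epoch {ep}, column "
                f"{self.feature_names[col]!r}"
            )

    @property
    def band_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def select_bands(self, bands: list[str]) -> "FeatureMatrix":
        """Column subset restricted to ``bands`` (order preserved)."""
        mask = np.isin(self.groups, bands)
        if not mask.any():
            raise KeyError(f"no features for bands {bands}")
        return replace(
            self,
            X=self.X[:, mask],
            feature_names=[n for n, m in zip(self.feature_names, mask) if m],
            groups=self.groups[mask],
        )


# ---------------------------------------------------------------------------
# ApEn / SampEn
# ---------------------------------------------------------------------------

def _chebyshev_stack(x: np.ndarray, max_m: int) -> list[np.ndarray]:
    """Running Chebyshev distance matrices D_1 .. D_{max_m}.

    D_m[i, j] = max_{0<=k<m} |x[i+k] - x[j+k]| for i, j template starts.
    D_{m+1} is the elementwise max of the top-left block of D_m and the
    shifted scalar-distance matrix, so the whole stack costs O(max_m * N^2)
    with no embedded-vector materialisation.
    """
    a = np.abs(x[:, None] - x[None, :])
    out = [a]
    for m in range(2, max_m + 1):
        prev = out[-1]
        out.append(np.maximum(prev[:-1, :-1], a[m - 1 :, m - 1 :]))
    return out


def _check_series(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= m + 1:
        raise ValueError(f"series length {x.size} must exceed m+1={m + 1}")
    return x


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r, N) with self-matches included.

    ``r`` is in signal units; if None it defaults to 0.2 * SD(x). A
    zero-variance series makes r = 0 and the statistic ill-defined; 0 is
    returned with a warning (a flat channel carries no irregularity).
    """
    x = _check_series(x, m)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        warnings.warn("zero-variance series: ApEn undefined, returning 0.0")
        return 0.0
    d = _chebyshev_stack(x, m + 1)
    phis = []
    for mm in (m, m + 1):
        dm = d[mm - 1]
        n_templ = dm.shape[0]
        c = np.count_nonzero(dm <= r, axis=1) / n_templ  # self-match included
        phis.append(np.log(c).mean())
    return float(phis[0] - phis[1])


def sample_entropy(x: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r, N) = -ln(A/B), self-matches excluded.

    B counts m-length template matches, A counts (m+1)-length matches, both
    over the N-m templates for which an (m+1)-length continuation exists and
    both normalised by (N-m-1). Returns NaN if no matches exist at either
    length (undefined ratio); callers exclude and log such epochs.
    """
    x = _check_series(x, m)
    if r is None:
        r = 0.15 * x.std()
    if r <= 0:
        warnings.warn("zero-variance series: SampEn undefined, returning 0.0")
        return 0.0
    d = _chebyshev_stack(x, m + 1)
    n = x.size
    n_templ = n - m  # templates with an (m+1)-length continuation
    b = np.count_nonzero(d[m - 1][:n_templ, :n_templ] <= r, axis=1) - 1
    a = np.count_nonzero(d[m] <= r, axis=1) - 1
    b_mean = b.sum() / (n_templ * (n - m - 1))
    a_mean = a.sum() / (n_templ * (n - m - 1))
    if a_mean == 0 or b_mean == 0:
        return float("nan")
    return float(-np.log(a_mean / b_mean))


def apen_sampen_grid(
    x: np.ndarray,
    ms: tuple[int, ...] = (1, 2),
    r_sds: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25),
) -> dict[tuple[str, int, float], float]:
    """ApEn and SampEn over a full (m, r_sd) grid from one distance stack.

    The Chebyshev stack dominates the cost and is shared across all grid
    cells, which is what makes the parameter grid search affordable.
    Returns {(measure, m, r_sd): value}; r = r_sd * SD(x).
    """
    max_m = max(ms) + 1
    x = _check_series(x, max_m - 1)
    sd = x.std()
    out: dict[tuple[str, int, float], float] = {}
    if sd == 0:
        warnings.warn("zero-variance series: ApEn/SampEn undefined, returning 0.0")
        for m in ms:
            for r_sd in r_sds:
                out[("apen", m, r_sd)] = 0.0
                out[("sampen", m, r_sd)] = 0.0
        return out
    d = _chebyshev_stack(x, max_m)
    n = x.size
    for r_sd in r_sds:
        r = r_sd * sd
        # row match counts per distance matrix, shared by ApEn (all m) and
        # the SampEn (m+1)-length numerators
        row_counts = [(dm <= r).sum(axis=1) for dm in d]
        phi = [np.log(rc / dm.shape[0]).mean() for rc, dm in zip(row_counts, d)]
        for m in ms:
            out[("apen", m, r_sd)] = float(phi[m - 1] - phi[m])
            n_templ = n - m
            b_total = int((d[m - 1][:n_templ, :n_templ] <= r).sum()) - n_templ
            a_total = int(row_counts[m].sum()) - d[m].shape[0]
            denom = n_templ * (n - m - 1)
            a_mean, b_mean = a_total / denom, b_total / denom
            out[("sampen", m, r_sd)] = (
                float("nan") if a_mean == 0 or b_mean == 0
                else float(-np.log(a_mean / b_mean))
            )
    return out


# ---------------------------------------------------------------------------
# Spectral entropy
# ---------------------------------------------------------------------------

def spectral_entropy_from_psd(p: np.ndarray) -> float:
    """Normalised Shannon entropy of a power distribution: in [0, 1].

    ``p`` need not be normalised; zero bins contribute nothing.
    """
    p = np.asarray(p, dtype=float)
    tot = p.sum()
    if tot <= 0:
        raise ValueError("all-zero spectrum: spectral entropy undefined")
    p = p / tot
    nz = p[p > 0]
    omega = p.size
    return float(-(nz * np.log(nz)).sum() / np.log(omega))


def spectral_entropy(
    x: np.ndarray,
    fs: float,
    seg_s: float = 1.0,
    overlap: float = 0.5,
) -> float:
    """Welch-PSD spectral entropy: Hamming segments of ``seg_s`` seconds.

    Ω is the number of PSD bins up to fs/2 returned by Welch's method.
    """
    x = np.asarray(x, dtype=float).ravel()
    nperseg = int(round(seg_s * fs))
    if x.size < nperseg:
        raise ValueError("series shorter than one Welch segment")
    _, psd = signal.welch(
        x, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
    )
    return spectral_entropy_from_psd(psd)


# ---------------------------------------------------------------------------
# SVD entropy
# ---------------------------------------------------------------------------

def _delay_embed(x: np.ndarray, emb: int, tau: int) -> np.ndarray:
    n_rows = x.size - (emb - 1) * tau
    if n_rows < emb:
        raise ValueError(
            f"series too short for embedding dim {emb}, delay {tau}"
        )
    idx = np.arange(n_rows)[:, None] + tau * np.arange(emb)[None, :]
    return x[idx]


def svd_entropy(x: np.ndarray, emb: int = 10, tau: int = 2) -> float:
    """Entropy of normalised squared singular values of the delay embedding.

    A single log base (2) is used for both the entropy sum and the 1/log L
    normalisation, so the value lies in [0, 1] with equal singular values
    mapping to exactly 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    h = _delay_embed(x, emb, tau)
    sv = np.linalg.svd(h, compute_uv=False)
    power = sv**2
    tot = power.sum()
    if tot <= 0:
        raise ValueError("all-zero series: SVD entropy undefined")
    p = power / tot
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(p.size))


# ---------------------------------------------------------------------------
# Renyi entropy
# ---------------------------------------------------------------------------

def renyi_entropy_from_probs(p: np.ndarray, alpha: float = 2.0) -> float:
    """Order-α Rényi entropy (bits) of a probability vector."""
    if not (alpha >= 0 and alpha != 1):
        raise ValueError("alpha must be >= 0 and != 1")
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    nz = p[p > 0]
    return float(np.log2((nz**alpha).sum()) / (1.0 - alpha))


def renyi_entropy(x: np.ndarray, alpha: float = 2.0, n_bins: int = 100) -> float:
    """Rényi entropy of the amplitude distribution of the series.

    The distribution is estimated with an equal-width histogram of ``n_bins``
    bins over the epoch's observed amplitude range — the main replication
    degree of freedom of this estimator, hence configurable. A constant
    series occupies a single bin and returns 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    return renyi_entropy_from_probs(counts / x.size, alpha)


# ---------------------------------------------------------------------------
# Wavelet entropy
# ---------------------------------------------------------------------------

def morlet_level_energies(
    x: np.ndarray,
    fs: float,
    n_scales: int = 10,
    fmin: float = 0.5,
    fmax: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level mean Morlet CWT energies and their centre frequencies.

    Scales are log-spaced so their centre frequencies cover [fmin, fmax];
    level energy is the mean of squared coefficients over the window (the
    whole epoch here — one value per epoch per channel).
    """
    x = np.asarray(x, dtype=float).ravel()
    freqs = np.geomspace(fmin, fmax, n_scales)
    scales = pywt.frequency2scale("morl", freqs / fs)
    coef, actual_freqs = pywt.cwt(x, scales, "morl", sampling_period=1.0 / fs)
    energies = (coef**2).mean(axis=1)
    return energies, actual_freqs


def wavelet_entropy_from_energies(energies: np.ndarray) -> float:
    """Shannon entropy (nats) of relative level energies: in [0, ln J]."""
    e = np.asarray(energies, dtype=float)
    tot = e.sum()
    if tot <= 0:
        raise ValueError("zero total wavelet energy: entropy undefined")
    p = e / tot
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def wavelet_entropy(
    x: np.ndarray,
    fs: float,
    n_scales: int = 10,
    fmin: float = 0.5,
    fmax: float = 40.0,
) -> float:
    energies, _ = morlet_level_energies(x, fs, n_scales, fmin, fmax)
    return wavelet_entropy_from_energies(energies)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

MEASURES = ("apen", "sampen", "spec", "svd", "renyi", "wavelet")


def _epoch_value(measure: str, x: np.ndarray, fs: float, p: EntropyParams) -> float:
    if measure == "apen":
        return approximate_entropy(x, p.apen_m, p.apen_r_sd * x.std())
    if measure == "sampen":
        return sample_entropy(x, p.sampen_m, p.sampen_r_sd * x.std())
    if measure == "spec":
        return spectral_entropy(x, fs, p.welch_seg_s, p.welch_overlap)
    if measure == "svd":
        return svd_entropy(x, p.svd_emb, p.svd_tau)
    if measure == "renyi":
        return renyi_entropy(x, p.alpha, p.n_hist_bins)
    if measure == "wavelet":
        return wavelet_entropy(x, fs, p.wavelet_n_scales, p.wavelet_fmin, p.wavelet_fmax)
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


def extract_features(
    banded_epochs,
    measure: str,
    params: EntropyParams | None = None,
    bands: list[str] | str = "all",
) -> FeatureMatrix:
    """One entropy value per (epoch, channel) for each requested band.

    ``banded_epochs`` is a mapping band name -> EpochSet (as produced by
    ``preprocess.decompose_bands``) or a single EpochSet. ``bands`` may be a
    list of band names or "all" (every band present, in mapping order).
    Feature blocks are concatenated column-wise; column names are
    ``band/channel`` and ``groups`` carries the per-column band name. The
    tolerance for ApEn/SampEn is recomputed per epoch per channel as
    r = r_sd * SD of that series.
    """
    params = params or EntropyParams()
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if hasattr(banded_epochs, "data"):  # single EpochSet
        banded_epochs = {banded_epochs.band: banded_epochs}
    if bands == "all":
        bands = list(banded_epochs)
    missing = [b for b in bands if b not in banded_epochs]
    if missing:
        raise KeyError(f"bands not present: {missing}")

    blocks, names, groups = [], [], []
    labels = subject_ids = None
    for band in bands:
        es = banded_epochs[band]
        n_ep, n_ch, _ = es.data.shape
        block = np.empty((n_ep, n_ch))
        for e in range(n_ep):
            for c in range(n_ch):
                block[e, c] = _epoch_value(measure, es.data[e, c], es.fs, params)
        bad = np.argwhere(~np.isfinite(block))
        if bad.size:
            e, c = bad[0]
            raise ValueError(
                f"non-finite {measure} feature: band {band!r}, epoch {e}, "
                f"channel {es.channels[c]!r}"
            )
        blocks.append(block)
        names.extend(f"{band}/{ch}" for ch in es.channels)
        groups.extend([band] * n_ch)
        if labels is None:
            labels, subject_ids = es.class_labels, es.subject_ids
        elif not (np.array_equal(labels, es.class_labels)
                  and np.array_equal(subject_ids, es.subject_ids)):
            raise ValueError("band EpochSets have mismatched epoch labels")

    return FeatureMatrix(
        X=np.hstack(blocks),
        feature_names=names,
        groups=np.array(groups),
        labels=np.asarray(labels),
        subject_ids=np.asarray(subject_ids),
        measure=measure,
        params=params,
    )
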