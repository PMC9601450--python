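"""Estimator correctness: brute-force oracles, analytic limits, invariances.

The oracles here are written independently of the implementation paths:
ApEn/SampEn against explicit embedded-vector Chebyshev distance matrices
(scipy cdist), SVD entropy against a Gram-matrix eigen-solve, spectral and
Rényi entropies against direct closed forms, wavelet entropy against direct
CWT energy accounting.
"""

import numpy as np
import pytest
from scipy import signal
from scipy.spatial.distance import cdist

from pnesent.entropy import (
    EntropyParams,
    apen_sampen_grid,
    approximate_entropy,
    extract_features,
    morlet_level_energies,
    renyi_entropy,
    renyi_entropy_from_probs,
    sample_entropy,
    spectral_entropy,
    spectral_entropy_from_psd,
    svd_entropy,
    wavelet_entropy,
    wavelet_entropy_from_energies,
)

N = 2560
FS = 256.0


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def _embed(x, m):
    return np.lib.stride_tricks.sliding_window_view(x, m)


def apen_oracle(x, m, r):
    """Direct pairwise-count ApEn: self-matches included, natural log."""
    phis = []
    for mm in (m, m + 1):
        e = _embed(x, mm)
        d = cdist(e, e, "chebyshev")
        c = (d <= r).sum(axis=1) / e.shape[0]
        phis.append(np.log(c).mean())
    return phis[0] - phis[1]


def sampen_oracle(x, m, r):
    """Direct pairwise-count SampEn: self-matches excluded."""
    n = len(x)
    em = _embed(x, m)[: n - m]
    b = ((cdist(em, em, "chebyshev") <= r).sum(axis=1) - 1).sum()
    e1 = _embed(x, m + 1)
    a = ((cdist(e1, e1, "chebyshev") <= r).sum(axis=1) - 1).sum()
    denom = (n - m) * (n - m - 1)
    return -np.log((a / denom) / (b / denom))


def svd_oracle(x, emb, tau):
    """Eigen-solve of the Gram matrix H H^T instead of singular values."""
    n_rows = len(x) - (emb - 1) * tau
    idx = np.arange(n_rows)[:, None] + tau * np.arange(emb)[None, :]
    h = x[idx]
    eig = np.linalg.eigvalsh(h.T @ h)  # emb x emb Gram
    eig = np.clip(eig, 0, None)
    p = eig / eig.sum()
    nz = p[p > 0]
    return -(nz * np.log2(nz)).sum() / np.log2(emb)


def renyi_oracle(x, alpha, bins):
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    return np.log2((p[p > 0] ** alpha).sum()) / (1 - alpha)


def wavelet_oracle(x, fs, n_scales, fmin, fmax):
    import pywt

    freqs = np.geomspace(fmin, fmax, n_scales)
    scales = pywt.frequency2scale("morl", freqs / fs)
    coef, _ = pywt.cwt(x, scales, "morl", sampling_period=1.0 / fs)
    e = (coef**2).mean(axis=1)
    p = e / e.sum()
    return -(p * np.log(p)).sum()


def spec_oracle(x, fs):
    _, psd = signal.welch(x, fs=fs, window="hamming", nperseg=int(fs),
                          noverlap=int(fs) // 2)
    p = psd / psd.sum()
    nz = p[p > 0]
    return -(nz * np.log(nz)).sum() / np.log(p.size)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_all_estimators_match_oracles(seed):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.standard_normal(N)) if seed % 2 else rng.standard_normal(N)
    sd = x.std()
    assert approximate_entropy(x, 2, 0.2 * sd) == pytest.approx(
        apen_oracle(x, 2, 0.2 * sd), abs=1e-10)
    assert sample_entropy(x, 1, 0.15 * sd) == pytest.approx(
        sampen_oracle(x, 1, 0.15 * sd), abs=1e-10)
    assert svd_entropy(x, 10, 2) == pytest.approx(svd_oracle(x, 10, 2), abs=1e-8)
    assert renyi_entropy(x, 2, 100) == pytest.approx(renyi_oracle(x, 2, 100), abs=1e-10)
    assert spectral_entropy(x, FS) == pytest.approx(spec_oracle(x, FS), abs=1e-10)
    assert wavelet_entropy(x, FS) == pytest.approx(
        wavelet_oracle(x, FS, 10, 0.5, 40.0), abs=1e-8)


def test_apen_grid_matches_individual_calls():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(N)
    grid = apen_sampen_grid(x)
    sd = x.std()
    for m in (1, 2):
        for r_sd in (0.1, 0.25):
            assert grid[("apen", m, r_sd)] == pytest.approx(
                approximate_entropy(x, m, r_sd * sd), abs=1e-12)
            assert grid[("sampen", m, r_sd)] == pytest.approx(
                sample_entropy(x, m, r_sd * sd), abs=1e-12)


def test_apen_ar1_sinusoid_reference_values():
    """Frozen values from the brute-force oracles on seeded inputs."""
    t = np.arange(N) / FS
    x = np.sin(2 * np.pi * 4 * t)
    assert approximate_entropy(x, 2, 0.2 * x.std()) == pytest.approx(
        apen_oracle(x, 2, 0.2 * x.std()), abs=1e-10)
    rng = np.random.default_rng(42)
    ar = np.empty(N)
    ar[0] = rng.standard_normal()
    eps = rng.standard_normal(N)
    for i in range(1, N):
        ar[i] = 0.9 * ar[i - 1] + eps[i]
    assert sample_entropy(ar, 1, 0.15 * ar.std()) == pytest.approx(
        sampen_oracle(ar, 1, 0.15 * ar.std()), abs=1e-10)


# ---------------------------------------------------------------------------
# Analytic limits and degenerate inputs
# ---------------------------------------------------------------------------

def test_constant_series_limits():
    x = np.full(512, 3.14)
    assert approximate_entropy(x, 2, r=0.5) == pytest.approx(0.0)
    assert sample_entropy(x, 1, r=0.5) == pytest.approx(0.0)
    assert svd_entropy(x + 1.0, 10, 2) == pytest.approx(0.0, abs=1e-12)
    assert renyi_entropy(x) == 0.0
    # zero-variance series with SD-derived tolerance: defined fallback + warning
    with pytest.warns(UserWarning):
        assert approximate_entropy(x, 2, r=None) == 0.0
    with pytest.warns(UserWarning):
        assert sample_entropy(x, 1, r=None) == 0.0


def test_spectral_entropy_closed_forms():
    omega = 64
    assert spectral_entropy_from_psd(np.ones(omega)) == pytest.approx(1.0)
    p = np.zeros(omega)
    p[3] = 1.0
    assert spectral_entropy_from_psd(p) == pytest.approx(0.0)
    p = np.zeros(omega)
    p[3] = p[40] = 0.5
    assert spectral_entropy_from_psd(p) == pytest.approx(np.log(2) / np.log(omega))
    with pytest.raises(ValueError):
        spectral_entropy_from_psd(np.zeros(8))


def test_renyi_closed_forms():
    omega = 32
    assert renyi_entropy_from_probs(np.ones(omega) / omega, 2) == pytest.approx(
        np.log2(omega))
    assert renyi_entropy_from_probs(np.array([0.5, 0.25, 0.25]), 2) == pytest.approx(
        -np.log2(0.375))
    one = np.zeros(10)
    one[4] = 1.0
    assert renyi_entropy_from_probs(one, 2) == pytest.approx(0.0)


def test_wavelet_entropy_limits():
    j = 10
    e = np.zeros(j)
    e[2] = 5.0
    assert wavelet_entropy_from_energies(e) == pytest.approx(0.0)
    assert wavelet_entropy_from_energies(np.ones(j)) == pytest.approx(np.log(j))
    with pytest.raises(ValueError):
        wavelet_entropy_from_energies(np.zeros(j))


def test_svd_entropy_two_equal_singular_values():
    # period-4 pattern embeds (emb=2, tau=1) into rows (1,0),(0,-1),(-1,0),
    # (0,1): orthogonal directions of near-equal power -> entropy ~ 1
    x = np.tile([1.0, 0.0, -1.0, 0.0], 64)
    assert svd_entropy(x, emb=2, tau=1) == pytest.approx(1.0, abs=1e-4)


def test_wavelet_peak_level_tracks_tone_frequency():
    t = np.arange(N) / FS
    x = np.sin(2 * np.pi * 6 * t)
    energies, freqs = morlet_level_energies(x, FS, n_scales=10, fmin=2, fmax=32)
    peak_freq = freqs[np.argmax(energies)]
    assert abs(np.log(peak_freq / 6.0)) == min(
        abs(np.log(freqs / 6.0)))  # nearest scale wins


# ---------------------------------------------------------------------------
# Invariances and orderings
# ---------------------------------------------------------------------------

def test_sampen_scale_invariance_with_rsd_parameterisation():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(800)
    a = sample_entropy(x, 1, 0.15 * x.std())
    y = 37.0 * x
    b = sample_entropy(y, 1, 0.15 * y.std())
    assert a == pytest.approx(b, abs=1e-12)


def test_noise_exceeds_sinusoid_complexity():
    """White noise scores above a matched-variance pure tone (20 seeds)."""
    t = np.arange(N) / FS
    tone = np.sin(2 * np.pi * 4 * t)
    tone_scores = {
        "apen": approximate_entropy(tone, 2, 0.2 * tone.std()),
        "sampen": sample_entropy(tone, 1, 0.15 * tone.std()),
        "spec": spectral_entropy(tone, FS),
        "wavelet": wavelet_entropy(tone, FS),
    }
    wins = {k: 0 for k in tone_scores}
    n_trials = 20
    for seed in range(n_trials):
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(N) * tone.std()
        if approximate_entropy(noise, 2, 0.2 * noise.std()) > tone_scores["apen"]:
            wins["apen"] += 1
        if sample_entropy(noise, 1, 0.15 * noise.std()) > tone_scores["sampen"]:
            wins["sampen"] += 1
        if spectral_entropy(noise, FS) > tone_scores["spec"]:
            wins["spec"] += 1
        if wavelet_entropy(noise, FS) > tone_scores["wavelet"]:
            wins["wavelet"] += 1
    for k, w in wins.items():
        assert w >= 19, f"{k}: noise beat the tone only {w}/{n_trials} times"


def test_normalised_estimators_bounded():
    rng = np.random.default_rng(11)
    for _ in range(10):
        x = rng.standard_normal(600)
        assert 0.0 <= spectral_entropy(x, FS) <= 1.0
        assert 0.0 <= svd_entropy(x, 10, 2) <= 1.0
        assert 0.0 <= renyi_entropy(x, 2, 100) <= np.log2(100)
        assert 0.0 <= wavelet_entropy(x, FS) <= np.log(10)


def test_sampen_stable_across_disjoint_epochs():
    rng = np.random.default_rng(2)
    vals = [
        sample_entropy(rng.standard_normal(N), 1, None) for _ in range(20)
    ]
    vals = np.array(vals)
    assert vals.std() / vals.mean() < 0.15


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def test_feature_matrix_shapes_and_groups(small_banded):
    fm1 = extract_features(small_banded, "renyi", bands=["theta"])
    n_ep = small_banded["theta"].n_epochs
    assert fm1.X.shape == (n_ep, 21)
    fm_all = extract_features(small_banded, "renyi")
    assert fm_all.X.shape == (n_ep, 21 * 6)
    for band in small_banded:
        assert (fm_all.groups == band).sum() == 21


def test_duplicated_epoch_gives_identical_feature_rows(small_banded):
    fm = extract_features(small_banded, "svd", bands=["broad"])
    es = small_banded["broad"]
    import dataclasses

    dup = dataclasses.replace(
        es,
        data=np.concatenate([es.data[:1], es.data[:1]]),
        subject_ids=es.subject_ids[:1].repeat(2),
        class_labels=es.class_labels[:1].repeat(2),
    )
    fm2 = extract_features({"broad": dup}, "svd", bands=["broad"])
    np.testing.assert_array_equal(fm2.X[0], fm2.X[1])
    np.testing.assert_allclose(fm2.X[0], fm.X[0])


def test_unknown_measure_and_params_validation(small_banded):
    with pytest.raises(ValueError):
        extract_features(small_banded, "shannon")
    with pytest.raises(ValueError):
        EntropyParams(apen_m=3)
    with pytest.raises(ValueError):
        EntropyParams(alpha=1.0)
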