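"""Shared fixtures: tiny synthetic spectra and cohorts built at test time."""

import numpy as np
import pytest

import serumpeaks as sp


def gaussian_spectrum(
    mz_lo=900.0,
    mz_hi=10500.0,
    step=1.0,
    peaks=(),
    baseline_amp=0.0,
    baseline_decay=2000.0,
    noise_sd=0.0,
    seed=0,
):
    """Spectrum = sum of Gaussians + exponential baseline + white noise."""
    rng = np.random.default_rng(seed)
    mz = np.arange(mz_lo, mz_hi + step / 2, step)
    y = np.zeros_like(mz)
    for center, height, sigma in peaks:
        y += height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
    y += baseline_amp * np.exp(-(mz - mz_lo) / baseline_decay)
    if noise_sd > 0:
        y += rng.normal(0, noise_sd, len(mz))
    return mz, np.clip(y, 0, None)


@pytest.fixture
def single_peak_spectrum():
    """One clean Gaussian at 2084 Da on the default grid."""
    mz, y = gaussian_spectrum(peaks=[(2084.0, 500.0, 4.0)])
    return sp.RawSpectrum(sample_id="s1", mz=mz, intensity=y)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort: 16+20 samples, 40 clusters, fast to process."""
    cfg = sp.SyntheticCohortConfig(
        n_hc=16, n_crc=20, n_common_peaks=40, random_seed=123
    )
    return sp.generate_spectra(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """Peak matrix of the reduced cohort (full preprocessing chain)."""
    spectra, manifest, truth = small_cohort
    processed, _ = sp.preprocess_cohort(spectra)
    peaks = []
    for s in processed:
        peaks.extend(sp.detect_peaks(s))
    groups = dict(zip(manifest["sample_id"], manifest["group"]))
    matrix = sp.cluster_peaks(
        peaks, samples=[s.sample_id for s in spectra], groups=groups
    )
    return matrix, truth


def separable_matrix(n_per_group=10, n_noise=0, gap=10.0, eps=0.1, seed=0):
    """PeakMatrix with one perfectly separating feature + optional noise features."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    cols = [np.concatenate([rng.normal(0, eps, n_per_group) ** 2,
                            gap + rng.normal(0, eps, n_per_group)])]
    for _ in range(n_noise):
        cols.append(rng.lognormal(3, 1, n))
    values = np.column_stack(cols)
    cluster_mz = 1000.0 + 100.0 * np.arange(values.shape[1])
    return sp.PeakMatrix(
        cluster_mz=cluster_mz,
        samples=[f"s{i}" for i in range(n)],
        groups=["HC"] * n_per_group + ["CRC"] * n_per_group,
        values=np.abs(values),
    )
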