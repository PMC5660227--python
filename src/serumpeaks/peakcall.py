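"""Per-spectrum peak detection and cross-sample peak clustering.

Detection finds strict local maxima whose height exceeds ``snr_min`` times
the spectrum's robust noise scale, suppresses the smaller of two maxima
closer than the minimum separation (0.3% of m/z by default, matching
linear-mode TOF mass accuracy), and reports an intensity-weighted centroid
over the three points around each apex.

Clustering walks all samples' peaks in ascending m/z with a running-centroid
single-linkage rule: a peak farther than ``tol_rel * centroid`` from the
current cluster's centroid starts a new cluster. Clusters present in fewer
than ``min_prevalence`` of the samples are dropped. The result is the
samples x peak-cluster intensity matrix exchanged by all downstream modules;
a sample without a peak in a cluster contributes intensity 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ValidationError
from .preprocess import ProcessedSpectrum

logger = logging.getLogger(__name__)

#: ClinProTools-style default; S/N 3 lets wavelet-ringing sidelobes of
#: strong peaks (~10% of the parent height) through as spurious features
DEFAULT_SNR_MIN = 5.0
DEFAULT_TOL_REL = 0.003
DEFAULT_MIN_PREVALENCE = 0.1


@dataclass
class Peak:
    """One detected peak in one sample's spectrum."""

    mz_centroid: float
    height: float
    snr: float
    sample_id: str

    def __post_init__(self):
        if self.height <= 0:
            raise ValidationError("peak height must be > 0")
        if self.snr < 0:
            raise ValidationError("peak snr must be >= 0")


@dataclass
class PeakMatrix:
    """Samples x peak-cluster intensity table with per-sample group labels."""

    cluster_mz: np.ndarray
    samples: list
    groups: list
    values: np.ndarray
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cluster_mz = np.asarray(self.cluster_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.cluster_mz)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.cluster_mz)} clusters"
            )
        if len(self.groups) != len(self.samples):
            raise ValidationError("groups length must match samples")
        if len(self.cluster_mz) > 1 and np.any(np.diff(self.cluster_mz) <= 0):
            raise ValidationError("cluster_mz must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("matrix intensities must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_mz)

    def to_dataframe(self):
        import pandas as pd
        from .spectra_io import cluster_labels

        df = pd.DataFrame(self.values, columns=cluster_labels(self.cluster_mz))
        df.insert(0, "sample_id", self.samples)
        df.insert(1, "group", self.groups)
        return df

    def column(self, mz: float, tol_rel: float = DEFAULT_TOL_REL) -> int:
        """Index of the cluster matching ``mz`` within the relative tolerance."""
        diffs = np.abs(self.cluster_mz - mz)
        i = int(np.argmin(diffs))
        if diffs[i] > tol_rel * mz:
            raise KeyError(f"no cluster within {tol_rel:.3%} of {mz} Da")
        return i

    def subset(self, member_mz, tol_rel: float = DEFAULT_TOL_REL) -> "PeakMatrix":
        idx = [self.column(m, tol_rel) for m in member_mz]
        return PeakMatrix(
            cluster_mz=self.cluster_mz[idx],
            samples=list(self.samples),
            groups=list(self.groups),
            values=self.values[:, idx],
        )

    def equals(self, other: "PeakMatrix", rtol: float = 1e-6) -> bool:
        return (
            list(self.samples) == list(other.samples)
            and list(self.groups) == list(other.groups)
            and self.values.shape == other.values.shape
            and np.allclose(self.cluster_mz, other.cluster_mz, rtol=rtol)
            and np.allclose(self.values, other.values, rtol=rtol)
        )


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_peaks(
    s: ProcessedSpectrum,
    snr_min: float = DEFAULT_SNR_MIN,
    min_sep_da: float | None = None,
) -> list[Peak]:
    """Detect peaks in a fully preprocessed spectrum.

    ``min_sep_da=None`` uses the mass-dependent default of 0.3% of m/z.
    Requires the spectrum to carry a noise scale (from denoising) and to have
    been normalized, so SNR and heights are comparable across samples.
    """
    if s.noise_scale is None:
        raise ParameterError(
            f"{s.sample_id}: no noise_scale on spectrum; run denoise_udwt first"
        )
    if "normalize_tic" not in s.steps():
        raise ParameterError(
            f"{s.sample_id}: spectrum not normalized; run the preprocessing chain first"
        )
    y, mz = s.intensity, s.mz
    interior = np.arange(1, len(y) - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    apex = interior[is_max]
    noise = max(s.noise_scale, np.finfo(float).tiny)
    apex = apex[y[apex] / noise >= snr_min]
    if len(apex) == 0:
        return []
    # greedy suppression: keep taller of any pair closer than the separation
    order = apex[np.argsort(-y[apex], kind="stable")]
    kept: list[int] = []
    kept_mz: list[float] = []
    for i in order:
        sep = min_sep_da if min_sep_da is not None else DEFAULT_TOL_REL * mz[i]
        if all(abs(mz[i] - km) >= sep for km in kept_mz):
            kept.append(i)
            kept_mz.append(mz[i])
    kept.sort()
    peaks = []
    for i in kept:
        sl = slice(i - 1, i + 2)
        w = y[sl]
        centroid = float(np.average(mz[sl], weights=w)) if w.sum() > 0 else float(mz[i])
        peaks.append(
            Peak(
                mz_centroid=centroid,
                height=float(y[i]),
                snr=float(y[i] / noise),
                sample_id=s.sample_id,
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_peaks(
    peaks: list[Peak],
    tol_rel: float = DEFAULT_TOL_REL,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    samples: list | None = None,
    groups: dict | None = None,
) -> PeakMatrix:
    """Cluster all samples' peaks along m/z into a :class:`PeakMatrix`.

    Parameters
    ----------
    peaks:
        Peaks pooled over every sample.
    tol_rel:
        Relative m/z tolerance; a peak farther than ``tol_rel * centroid``
        from the running cluster centroid starts a new cluster.
    min_prevalence:
        Clusters detected in a smaller fraction of samples are dropped.
    samples:
        Sample order for the matrix rows. Defaults to the sorted set of
        sample ids contributing peaks; pass explicitly to include samples
        with no detected peaks and to fix row order.
    groups:
        Optional ``sample_id -> group`` mapping for the matrix's group column.
    """
    if tol_rel <= 0:
        raise ParameterError("tol_rel must be > 0")
    if not 0 <= min_prevalence <= 1:
        raise ParameterError("min_prevalence must be in [0, 1]")
    if samples is None:
        samples = sorted({p.sample_id for p in peaks})
    if len(samples) < 2:
        raise ParameterError("clustering requires peaks from >= 2 samples")

    # deterministic order independent of input permutation
    ordered = sorted(peaks, key=lambda p: (p.mz_centroid, p.sample_id, -p.height))
    clusters: list[list[Peak]] = []
    centroid = None
    total = 0.0
    for p in ordered:
        if centroid is not None and (p.mz_centroid - centroid) <= tol_rel * centroid:
            clusters[-1].append(p)
            total += p.mz_centroid
            centroid = total / len(clusters[-1])
        else:
            clusters.append([p])
            total = p.mz_centroid
            centroid = p.mz_centroid

    n_dropped_peaks = 0
    n_multi = 0
    kept: list[tuple[float, dict]] = []
    min_count = min_prevalence * len(samples)
    sample_set = set(samples)
    for members in clusters:
        per_sample: dict[str, float] = {}
        for p in members:
            if p.sample_id not in sample_set:
                raise ValidationError(f"peak from unknown sample {p.sample_id!r}")
            if p.sample_id in per_sample:
                n_multi += 1
                per_sample[p.sample_id] = max(per_sample[p.sample_id], p.height)
            else:
                per_sample[p.sample_id] = p.height
        if len(per_sample) < min_count:
            n_dropped_peaks += len(members)
            continue
        kept.append((float(np.mean([p.mz_centroid for p in members])), per_sample))

    kept.sort(key=lambda c: c[0])
    cluster_mz = np.array([c[0] for c in kept])
    values = np.zeros((len(samples), len(kept)))
    col_of = {i: j for j, i in enumerate(range(len(kept)))}
    row_of = {sid: i for i, sid in enumerate(samples)}
    for j, (_, per_sample) in enumerate(kept):
        for sid, h in per_sample.items():
            values[row_of[sid], j] = h
    if n_dropped_peaks:
        logger.info(
            "dropped %d peaks in clusters below prevalence %.2f",
            n_dropped_peaks,
            min_prevalence,
        )
    group_list = [groups.get(sid) if groups else None for sid in samples]
    return PeakMatrix(
        cluster_mz=cluster_mz,
        samples=list(samples),
        groups=group_list,
        values=values,
        log={
            "n_input_peaks": len(peaks),
            "n_clusters_before_prevalence": len(clusters),
            "n_dropped_peaks": n_dropped_peaks,
            "n_multi_peak_cells": n_multi,
            "tol_rel": tol_rel,
            "min_prevalence": min_prevalence,
        },
    )
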