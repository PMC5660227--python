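"""Spectral preprocessing: mass-window restriction, undecimated-wavelet
denoising, baseline correction and total-ion-current normalization.

The pipeline order is fixed — restrict -> denoise -> baseline -> normalize —
and every step appends its parameters to the spectrum's processing log, so a
run is fully reproducible from the logged configuration.

Denoising uses the undecimated (stationary, shift-invariant) discrete wavelet
transform: detail coefficients are thresholded at ``k * sigma_hat`` where
``sigma_hat = MAD(finest details) / 0.6745`` is the robust noise scale, then
the transform is inverted. The noise scale is retained on the spectrum; peak
detection later expresses signal-to-noise ratios in its units.

Baseline correction is a smoothed morphological rolling-minimum (grey
opening): a rolling minimum over ``window_da`` followed by a rolling maximum
of the same width recovers slowly varying baseline exactly on monotone
segments while ignoring peaks narrower than the window; a mean filter over
``smooth_da`` removes the remaining staircase artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .exceptions import ParameterError, ValidationError
from .spectra_io import RawSpectrum

logger = logging.getLogger(__name__)

THRESHOLD_RULES = ("universal", "visu-soft", "visu-hard")

#: default analysis mass window in Da
MASS_LO = 900.0
MASS_HI = 10500.0


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain (config block ``preprocess:``)."""

    mass_lo: float = MASS_LO
    mass_hi: float = MASS_HI
    wavelet: str = "db8"
    levels: int | None = None  # None -> min(6, floor(log2 n) - 2)
    threshold_rule: str = "universal"
    baseline_window_da: float = 200.0
    baseline_smooth_da: float = 100.0
    tic_target: float | None = None  # None -> cohort-mean TIC


@dataclass
class ProcessedSpectrum(RawSpectrum):
    """A spectrum plus its processing history and robust noise scale."""

    processing_log: list = field(default_factory=list)
    noise_scale: float | None = None

    # intermediate stages (post-denoise, pre-clip) may dip slightly negative
    _allow_negative_intensity = True

    @classmethod
    def from_raw(cls, s: RawSpectrum) -> "ProcessedSpectrum":
        if isinstance(s, ProcessedSpectrum):
            return s
        return cls(
            sample_id=s.sample_id,
            mz=s.mz.copy(),
            intensity=s.intensity.copy(),
            group=s.group,
            provenance=dict(s.provenance),
        )

    def steps(self) -> list[str]:
        return [entry["step"] for entry in self.processing_log]

    def _with(self, intensity=None, mz=None, log_entry=None, noise_scale=None):
        out = ProcessedSpectrum(
            sample_id=self.sample_id,
            mz=self.mz if mz is None else mz,
            intensity=self.intensity if intensity is None else intensity,
            group=self.group,
            provenance=dict(self.provenance),
            processing_log=list(self.processing_log),
            noise_scale=self.noise_scale if noise_scale is None else noise_scale,
        )
        if log_entry is not None:
            out.processing_log.append(log_entry)
        return out


def _as_processed(s: RawSpectrum) -> ProcessedSpectrum:
    return ProcessedSpectrum.from_raw(s)


# ---------------------------------------------------------------------------
# UDWT denoising
# ---------------------------------------------------------------------------


def default_levels(n: int) -> int:
    return max(1, min(6, int(np.floor(np.log2(n))) - 2))


def denoise_udwt(
    s: RawSpectrum,
    wavelet_name: str = "db8",
    levels: int | None = None,
    threshold_rule: str = "universal",
) -> ProcessedSpectrum:
    """Undecimated-wavelet denoising with a universal (VisuShrink) threshold.

    ``threshold_rule``: ``"universal"`` and ``"visu-soft"`` soft-threshold the
    detail coefficients at ``sqrt(2 ln n) * sigma_hat``; ``"visu-hard"`` uses
    the same threshold with hard thresholding.
    """
    if threshold_rule not in THRESHOLD_RULES:
        raise ParameterError(
            f"threshold_rule must be one of {THRESHOLD_RULES}, got {threshold_rule!r}"
        )
    s = _as_processed(s)
    n = len(s)
    if levels is None:
        levels = default_levels(n)
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    if n < 2**levels:
        raise ParameterError(
            f"spectrum of {n} points is shorter than the level-{levels} transform "
            "support; reduce `levels` or enable zero-padding of the input"
        )
    # stationary transform needs a length divisible by 2**levels: symmetric pad
    pad = (-n) % (2**levels)
    x = np.pad(s.intensity, (0, pad), mode="symmetric") if pad else s.intensity
    coeffs = pywt.swt(x, wavelet_name, level=levels, trim_approx=True, norm=False)
    # coeffs = [approx_L, detail_L, ..., detail_1]; finest detail is last
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest - np.median(finest))) / 0.6745)
    thr = sigma * np.sqrt(2.0 * np.log(n))
    if threshold_rule == "visu-hard":
        def shrink(d):
            return np.where(np.abs(d) > thr, d, 0.0)
    else:  # soft
        def shrink(d):
            return np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)

    den = [coeffs[0]] + [shrink(d) for d in coeffs[1:]]
    rec = pywt.iswt(den, wavelet_name, norm=False)[:n]
    return s._with(
        intensity=rec,
        noise_scale=sigma,
        log_entry={
            "step": "denoise_udwt",
            "wavelet": wavelet_name,
            "levels": levels,
            "threshold_rule": threshold_rule,
            "threshold": thr,
            "noise_scale": sigma,
        },
    )


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------


def estimate_baseline(
    mz: np.ndarray, intensity: np.ndarray, window_da: float, smooth_da: float
) -> np.ndarray:
    """Smoothed rolling-minimum (morphological opening) baseline estimate."""
    step = float(np.median(np.diff(mz)))
    w = max(3, int(round(window_da / step)) | 1)  # odd window
    # odd-reflection padding continues the edge trend linearly, so the
    # opening recovers a monotone baseline exactly up to the boundary
    # (plain reflection or replication bites a dip into a decaying edge)
    padded = np.pad(intensity, w, mode="reflect", reflect_type="odd")
    opened = maximum_filter1d(minimum_filter1d(padded, size=w), size=w)
    if smooth_da > 0:
        sw = max(1, int(round(smooth_da / step)))
        opened = uniform_filter1d(opened, size=sw)
    opened = opened[w:-w]
    # a baseline estimate is non-negative and never exceeds its signal
    return np.clip(opened, 0.0, intensity)


def correct_baseline(
    s: RawSpectrum, window_da: float = 200.0, smooth_da: float = 100.0
) -> ProcessedSpectrum:
    """Subtract a smoothed rolling-minimum baseline and clip negatives to 0."""
    if window_da <= 0:
        raise ParameterError("window_da must be > 0")
    if smooth_da < 0:
        raise ParameterError("smooth_da must be >= 0")
    s = _as_processed(s)
    baseline = estimate_baseline(s.mz, s.intensity, window_da, smooth_da)
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return s._with(
        intensity=corrected,
        log_entry={
            "step": "correct_baseline",
            "window_da": window_da,
            "smooth_da": smooth_da,
            "baseline_max": float(baseline.max()),
            "baseline_mean": float(baseline.mean()),
        },
    )


# ---------------------------------------------------------------------------
# Normalization and mass window
# ---------------------------------------------------------------------------


def normalize_tic(s: RawSpectrum, target: float = 1.0e6) -> ProcessedSpectrum:
    """Scale intensities so their sum (total ion current) equals ``target``."""
    if target <= 0:
        raise ParameterError("tic target must be > 0")
    s = _as_processed(s)
    tic = float(s.intensity.sum())
    if tic <= 0:
        raise ValidationError(f"{s.sample_id}: zero total ion current")
    factor = target / tic
    return s._with(
        intensity=s.intensity * factor,
        noise_scale=None if s.noise_scale is None else s.noise_scale * factor,
        log_entry={"step": "normalize_tic", "target": target, "scale_factor": factor},
    )


def restrict_mass_range(
    s: RawSpectrum, lo_da: float = MASS_LO, hi_da: float = MASS_HI
) -> ProcessedSpectrum:
    """Keep points with ``lo_da <= mz <= hi_da`` (closed interval)."""
    if lo_da >= hi_da:
        raise ParameterError(f"require lo_da < hi_da, got ({lo_da}, {hi_da})")
    s = _as_processed(s)
    mask = (s.mz >= lo_da) & (s.mz <= hi_da)
    if mask.sum() < 2:
        raise ValidationError(
            f"{s.sample_id}: mass window [{lo_da}, {hi_da}] leaves "
            f"{int(mask.sum())} points"
        )
    return s._with(
        mz=s.mz[mask],
        intensity=s.intensity[mask],
        log_entry={"step": "restrict_mass_range", "lo_da": lo_da, "hi_da": hi_da},
    )


# ---------------------------------------------------------------------------
# Whole-chain drivers
# ---------------------------------------------------------------------------


def preprocess_spectrum(
    s: RawSpectrum, config: PreprocessConfig = PreprocessConfig(), *,
    tic_target: float | None = None,
) -> ProcessedSpectrum:
    """Run restrict -> denoise -> baseline -> normalize on one spectrum.

    ``tic_target`` overrides ``config.tic_target`` (used by the cohort driver
    to normalize to the cohort-mean TIC).
    """
    out = restrict_mass_range(s, config.mass_lo, config.mass_hi)
    out = denoise_udwt(out, config.wavelet, config.levels, config.threshold_rule)
    out = correct_baseline(out, config.baseline_window_da, config.baseline_smooth_da)
    target = tic_target if tic_target is not None else config.tic_target
    if target is None:
        target = float(out.intensity.sum())  # single-spectrum fallback: self TIC
    return normalize_tic(out, target)


def preprocess_cohort(
    spectra: list[RawSpectrum],
    config: PreprocessConfig = PreprocessConfig(),
    tic_target: float | None = None,
) -> tuple[list[ProcessedSpectrum], float]:
    """Preprocess a cohort; returns ``(processed, tic_target_used)``.

    The TIC target defaults to the cohort-mean of the baseline-corrected
    (pre-normalization) total ion currents. Pass ``tic_target`` explicitly to
    normalize a later cohort (e.g. a blind test set) to the scale fixed on
    the training cohort — evaluation must not re-derive any parameter from
    test data.
    """
    partial = []
    for s in spectra:
        out = restrict_mass_range(s, config.mass_lo, config.mass_hi)
        out = denoise_udwt(out, config.wavelet, config.levels, config.threshold_rule)
        out = correct_baseline(out, config.baseline_window_da, config.baseline_smooth_da)
        partial.append(out)
    target = tic_target if tic_target is not None else config.tic_target
    if target is None:
        target = float(np.mean([p.intensity.sum() for p in partial]))
    return [normalize_tic(p, target) for p in partial], target
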