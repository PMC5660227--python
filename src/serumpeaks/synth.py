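"""Synthetic cohorts with known ground truth: labelled MALDI-TOF serum
spectra, ELISA-like clinical marker tables, and survival records.

The spectrum generator emulates a linear-mode MALDI-TOF serum profiling
study: ~173 peak clusters shared across the cohort on a 900-10,500 Da grid,
of which ten planted markers differ between healthy controls (HC) and
colorectal cancer (CRC) samples — three up-regulated in CRC (1781, 1868,
1694 Da) and seven down-regulated (2084, 1947, 6856, 1951, 2886, 2073,
4478 Da). Each spectrum is a sum of Gaussian peaks (width growing linearly
with m/z, mimicking TOF resolution), an exponentially decaying chemical
baseline, heteroscedastic Gaussian noise, and a per-spectrum multiplicative
gain that exercises TIC normalization downstream. Peak heights are
log-normal: serum profiling intensities are strongly right-skewed.

Everything is reproducible from the config seed, and the returned
:class:`GroundTruth` suffices to recompute every planted effect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .exceptions import ParameterError, ValidationError
from .spectra_io import RawSpectrum, validate_manifest

logger = logging.getLogger(__name__)

#: planted differential markers: [m/z in Da, direction, fold change]
#: (lists, not tuples, so configs round-trip through YAML unchanged)
DEFAULT_PLANTED = [
    [1694.0, "up_in_CRC", 2.5],
    [1781.0, "up_in_CRC", 2.5],
    [1868.0, "up_in_CRC", 2.5],
    [1947.0, "down_in_CRC", 2.5],
    [1951.0, "down_in_CRC", 2.5],
    [2073.0, "down_in_CRC", 2.5],
    [2084.0, "down_in_CRC", 2.5],
    [2886.0, "down_in_CRC", 2.5],
    [4478.0, "down_in_CRC", 2.5],
    [6856.0, "down_in_CRC", 2.5],
]

#: CRC stage proportions of the discovery cohort (stages I/II/III/IV)
STAGE_WEIGHTS = {"I": 25, "II": 36, "III": 48, "IV": 18}


@dataclass
class SyntheticCohortConfig:
    """Everything the spectrum generator needs; defaults emulate the study."""

    n_hc: int = 90
    n_crc: int = 127
    mass_lo: float = 900.0
    mass_hi: float = 10500.0
    grid_step: float = 1.0
    n_common_peaks: int = 173
    planted: list = field(default_factory=lambda: list(DEFAULT_PLANTED))
    # sigma = coeff * mz; 0.0008 puts the FWHM at ~1950 Da below the 4-Da
    # spacing of the closest reported marker pair (1947/1951), which the
    # instrument being emulated demonstrably resolved
    peak_width_coeff: float = 0.0008
    baseline_amp: float = 800.0
    baseline_decay: float = 2000.0  # Da
    noise_scale: float = 8.0
    gain_lo: float = 0.7
    gain_hi: float = 1.3
    height_log_mu: float = float(np.log(300.0))  # common-peak base heights
    height_log_sigma: float = 0.8
    planted_base_height: float = 400.0
    within_log_sigma: float = 0.6  # per-sample biological+technical spread
    min_rel_sep: float = 0.007  # between cluster masses (> 2x clustering tol)
    random_seed: int = 0

    def __post_init__(self):
        self.planted = [list(p) for p in self.planted]

    def validate(self) -> None:
        if self.n_hc < 0 or self.n_crc < 0:
            raise ParameterError("cohort sizes must be >= 0")
        if self.mass_lo >= self.mass_hi:
            raise ParameterError("mass_lo must be < mass_hi")
        if self.grid_step <= 0:
            raise ParameterError("grid_step must be > 0")
        for mz, direction, fold in self.planted:
            if not self.mass_lo <= mz <= self.mass_hi:
                raise ParameterError(f"planted mass {mz} outside mass window")
            if fold <= 0:
                raise ParameterError("fold_change must be > 0")
            if direction not in ("up_in_CRC", "down_in_CRC"):
                raise ParameterError(f"unknown direction {direction!r}")
        if self.n_common_peaks < len(self.planted):
            raise ParameterError("n_common_peaks must be >= number of planted peaks")
        planted_mz = sorted(mz for mz, _, _ in self.planted)
        for a, b in zip(planted_mz, planted_mz[1:]):
            if b - a < self.grid_step:
                raise ParameterError(
                    f"planted masses {a} and {b} are closer than the grid step"
                )


@dataclass
class ClusterTruth:
    mz: float
    is_planted: bool
    direction: str | None
    fold_change: float
    base_height: float


@dataclass
class GroundTruth:
    """Generator-side truth sufficient to recompute every planted effect."""

    sample_groups: dict
    clusters: list
    config: dict

    def planted_mz(self) -> list[float]:
        return [c.mz for c in self.clusters if c.is_planted]

    def count_recovered(self, panel_mz, tol_rel: float = 0.003) -> int:
        """Planted masses matched by at least one panel member within tolerance.

        Counted truth-side: planted peaks closer to each other than the
        clustering tolerance merge into one cluster, and a panel containing
        the merged cluster recovers every peptide it represents.
        """
        return sum(
            any(abs(m - p) <= tol_rel * p for m in panel_mz)
            for p in self.planted_mz()
        )

    def count_noise(self, panel_mz, tol_rel: float = 0.003) -> int:
        """Panel members matching no planted mass within tolerance."""
        planted = self.planted_mz()
        return sum(
            not any(abs(m - p) <= tol_rel * p for p in planted) for m in panel_mz
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_groups": self.sample_groups,
                "clusters": [asdict(c) for c in self.clusters],
                "config": self.config,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            sample_groups=d["sample_groups"],
            clusters=[ClusterTruth(**c) for c in d["clusters"]],
            config=d["config"],
        )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _draw_cluster_masses(cfg: SyntheticCohortConfig, rng: np.random.Generator):
    """Log-uniform cluster masses with a minimum relative separation.

    Log-uniform placement concentrates peaks at low mass, as serum profiles
    do, and makes the separation constraint uniformly feasible in relative
    terms across the window.
    """
    accepted = sorted(mz for mz, _, _ in cfg.planted)
    n_extra = cfg.n_common_peaks - len(accepted)
    lo = np.log(cfg.mass_lo + 30.0)
    hi = np.log(cfg.mass_hi - 100.0)
    attempts = 0
    while n_extra > 0:
        m = float(np.exp(rng.uniform(lo, hi)))
        if all(abs(m - a) / min(m, a) >= cfg.min_rel_sep for a in accepted):
            accepted.append(m)
            accepted.sort()
            n_extra -= 1
        attempts += 1
        if attempts > 200_000:
            raise ParameterError(
                "cannot place common peaks with the requested separation"
            )
    return np.array(accepted)


def generate_spectra(cfg: SyntheticCohortConfig | None = None):
    """Generate ``(spectra, manifest, truth)`` for one cohort.

    Cluster masses and base heights are drawn once per cohort; per-sample
    peak heights are log-normal around the group mean (mean-one multiplicative
    noise, so group means differ exactly by the configured fold change).
    """
    cfg = cfg or SyntheticCohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.random_seed)

    masses = _draw_cluster_masses(cfg, rng)
    planted_by_mz = {mz: (direction, fold) for mz, direction, fold in cfg.planted}

    base = np.exp(rng.normal(cfg.height_log_mu, cfg.height_log_sigma, len(masses)))
    base = np.clip(base, 80.0, 5000.0)
    clusters = []
    hc_mean = np.empty(len(masses))
    crc_mean = np.empty(len(masses))
    for k, mz in enumerate(masses):
        if mz in planted_by_mz:
            direction, fold = planted_by_mz[mz]
            h = cfg.planted_base_height
            hc_mean[k] = h
            crc_mean[k] = h * fold if direction == "up_in_CRC" else h / fold
            clusters.append(ClusterTruth(float(mz), True, direction, fold, h))
        else:
            hc_mean[k] = crc_mean[k] = base[k]
            clusters.append(ClusterTruth(float(mz), False, None, 1.0, float(base[k])))

    grid = np.arange(cfg.mass_lo, cfg.mass_hi + cfg.grid_step / 2, cfg.grid_step)
    sigma = cfg.peak_width_coeff * masses
    baseline = cfg.baseline_amp * np.exp(-(grid - cfg.mass_lo) / cfg.baseline_decay)
    # mildly heteroscedastic: detector noise decays a little with mass; a
    # strong mass dependence would defeat the single robust noise scale the
    # denoiser estimates per spectrum
    noise_sd = cfg.noise_scale * (0.7 + 0.3 * np.exp(-(grid - cfg.mass_lo) / cfg.baseline_decay))
    # precompute each peak's local grid support (+-5 sigma)
    spans = []
    for k, mz in enumerate(masses):
        i0 = int(np.searchsorted(grid, mz - 5 * sigma[k]))
        i1 = int(np.searchsorted(grid, mz + 5 * sigma[k]))
        shape = np.exp(-0.5 * ((grid[i0:i1] - mz) / sigma[k]) ** 2)
        spans.append((i0, i1, shape))

    # mean-one log-normal multiplicative noise
    mu_adj = -cfg.within_log_sigma**2 / 2.0

    spectra = []
    rows = []
    groups = {}
    stage_names = list(STAGE_WEIGHTS)
    stage_p = np.array(list(STAGE_WEIGHTS.values()), dtype=float)
    stage_p /= stage_p.sum()
    plan = [("HC", i) for i in range(cfg.n_hc)] + [("CRC", i) for i in range(cfg.n_crc)]
    for grp, i in plan:
        sid = f"{grp}{i + 1:03d}"
        mean_k = hc_mean if grp == "HC" else crc_mean
        heights = mean_k * np.exp(rng.normal(mu_adj, cfg.within_log_sigma, len(masses)))
        signal = np.zeros_like(grid)
        for k, (i0, i1, shape) in enumerate(spans):
            signal[i0:i1] += heights[k] * shape
        noise = rng.normal(0.0, 1.0, len(grid)) * noise_sd
        gain = rng.uniform(cfg.gain_lo, cfg.gain_hi)
        intensity = np.clip(gain * (signal + baseline + noise), 0.0, None)
        spectra.append(
            RawSpectrum(
                sample_id=sid,
                mz=grid.copy(),
                intensity=intensity,
                group=grp,
                provenance={"generator": "serumpeaks.synth", "gain": f"{gain:.6f}"},
            )
        )
        stage = (
            stage_names[rng.choice(len(stage_names), p=stage_p)] if grp == "CRC" else None
        )
        groups[sid] = grp
        rows.append({"sample_id": sid, "group": grp, "stage": stage})

    manifest = pd.DataFrame(
        rows, columns=["sample_id", "group", "stage"]
    )
    for col in ("cea", "fobt", "surv_months", "surv_event"):
        manifest[col] = np.nan
    if len(manifest):
        validate_manifest(manifest)
    truth = GroundTruth(
        sample_groups=groups, clusters=clusters, config=asdict(cfg)
    )
    return spectra, manifest, truth


def split_cohort(spectra, manifest, n_hc_train: int, n_crc_train: int):
    """Deterministically split a cohort into training and blind sets.

    The first ``n_hc_train`` HC and ``n_crc_train`` CRC samples (manifest
    order) form the training set, mirroring a first-day/second-day
    acquisition split; the remainder is the blind set.
    """
    by_group = {"HC": [], "CRC": []}
    for sid, grp in zip(manifest["sample_id"], manifest["group"]):
        by_group[grp].append(sid)
    if n_hc_train > len(by_group["HC"]) or n_crc_train > len(by_group["CRC"]):
        raise ParameterError("training split larger than the cohort")
    train_ids = set(by_group["HC"][:n_hc_train] + by_group["CRC"][:n_crc_train])
    train = [s for s in spectra if s.sample_id in train_ids]
    test = [s for s in spectra if s.sample_id not in train_ids]
    m_train = manifest[manifest["sample_id"].isin(train_ids)].reset_index(drop=True)
    m_test = manifest[~manifest["sample_id"].isin(train_ids)].reset_index(drop=True)
    return train, m_train, test, m_test


# ---------------------------------------------------------------------------
# Clinical marker table
# ---------------------------------------------------------------------------

#: MST1 ELISA concentration (ng/ml) mean/SD per group; HC, stage I and IV and
#: the pooled CRC values follow the reported validation cohort; stages II and
#: III are interpolated to keep the stage trend and the pooled mean consistent.
MST1_PARAMS = {
    "HC": (959.65, 407.07),
    "I": (343.97, 277.76),
    "II": (250.0, 261.99),
    "III": (230.0, 261.99),
    "IV": (132.49, 138.36),
}

#: CEA (ug/l) log-normal medians per stage and sigma of log; HC separately.
CEA_MEDIANS = {"HC": 1.8, "I": 2.5, "II": 3.6, "III": 5.5, "IV": 9.0}
CEA_LOG_SIGMA = {"HC": 0.6, "CRC": 1.0}

#: FOBT positivity rates (sensitivity-like in CRC, 1 - specificity in HC)
FOBT_RATE = {"HC": 0.0, "CRC": 0.641}

DEFAULT_CRC_BY_STAGE = {"I": 10, "II": 16, "III": 15, "IV": 10}


def _truncated_normal(rng, mean, sd, size):
    a = (0.0 - mean) / sd  # truncate at zero: concentrations are non-negative
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_clinical_table(
    n_hc: int = 16,
    n_crc_by_stage: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """ELISA-like table of (mst1, cea, fobt) per sample with stage labels.

    MST1 is drawn from zero-truncated normals with the per-group means/SDs
    above; CEA is log-normal with stage-increasing medians; FOBT is Bernoulli
    with rate 0.641 in CRC and 0 in HC.
    """
    n_crc_by_stage = DEFAULT_CRC_BY_STAGE if n_crc_by_stage is None else n_crc_by_stage
    for key in n_crc_by_stage:
        if key not in ("I", "II", "III", "IV"):
            raise ParameterError(f"unknown stage key {key!r}")
        if n_crc_by_stage[key] < 0:
            raise ParameterError("stage sizes must be >= 0")
    if n_hc < 0:
        raise ParameterError("n_hc must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    mean, sd = MST1_PARAMS["HC"]
    mst1_hc = _truncated_normal(rng, mean, sd, n_hc)
    cea_hc = np.exp(rng.normal(np.log(CEA_MEDIANS["HC"]), CEA_LOG_SIGMA["HC"], n_hc))
    fobt_hc = rng.random(n_hc) < FOBT_RATE["HC"]
    for i in range(n_hc):
        rows.append(
            {
                "sample_id": f"HC{i + 1:03d}",
                "group": "HC",
                "stage": None,
                "mst1": mst1_hc[i],
                "cea": cea_hc[i],
                "fobt": int(fobt_hc[i]),
            }
        )
    idx = 0
    for stage in ("I", "II", "III", "IV"):
        n = n_crc_by_stage.get(stage, 0)
        mean, sd = MST1_PARAMS[stage]
        mst1 = _truncated_normal(rng, mean, sd, n)
        cea = np.exp(rng.normal(np.log(CEA_MEDIANS[stage]), CEA_LOG_SIGMA["CRC"], n))
        fobt = rng.random(n) < FOBT_RATE["CRC"]
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "sample_id": f"CRC{idx:03d}",
                    "group": "CRC",
                    "stage": stage,
                    "mst1": mst1[i],
                    "cea": cea[i],
                    "fobt": int(fobt[i]),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "stage", "mst1", "cea", "fobt"]
    )


# ---------------------------------------------------------------------------
# Survival records
# ---------------------------------------------------------------------------


def generate_survival(
    n: int = 46,
    cutoff_truth: float | None = None,
    hazard_ratio: float = 4.0,
    censor_rate: float = 0.35,
    seed: int = 0,
    baseline_median_months: float = 120.0,
    expr_log_mu: float = float(np.log(500.0)),
    expr_log_sigma: float = 0.8,
) -> pd.DataFrame:
    """Survival records with exponential event times and uniform censoring.

    Subjects with expression below ``cutoff_truth`` (default: the median of
    the expression distribution) have their hazard multiplied by
    ``hazard_ratio`` — low marker expression confers poor prognosis. Censoring
    times are uniform on (0, c) with c solved so the expected censored
    fraction equals ``censor_rate``.
    """
    if hazard_ratio <= 0:
        raise ParameterError("hazard_ratio must be > 0")
    if not 0 <= censor_rate < 1:
        raise ParameterError("censor_rate must be in [0, 1)")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if cutoff_truth is None:
        cutoff_truth = float(np.exp(expr_log_mu))  # median of the log-normal
    cols = ["sample_id", "expression", "time", "event"]
    if n == 0:
        return pd.DataFrame(columns=cols)

    expression = np.exp(rng.normal(expr_log_mu, expr_log_sigma, n))
    lam0 = np.log(2.0) / baseline_median_months
    lam = np.where(expression < cutoff_truth, lam0 * hazard_ratio, lam0)
    event_times = rng.exponential(1.0 / lam)

    if censor_rate > 0:
        frac_low = float((expression < cutoff_truth).mean())
        means = np.array([1.0 / (lam0 * hazard_ratio), 1.0 / lam0])
        w = np.array([frac_low, 1.0 - frac_low])

        def expected_censored(c):
            # P(T > C) for T ~ Exp(mean m), C ~ U(0, c): (m/c) (1 - e^{-c/m})
            return float(np.sum(w * (means / c) * (1.0 - np.exp(-c / means)))) - censor_rate

        c_max = brentq(expected_censored, 1e-6, 1e7)
        censor_times = rng.uniform(0.0, c_max, n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time = event_times
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-3)  # survival times strictly positive

    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "expression": expression,
            "time": time,
            "event": event,
        },
        columns=cols,
    )
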