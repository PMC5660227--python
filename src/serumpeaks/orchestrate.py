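"""Configuration, seed management, logging and the end-to-end drivers.

``run_discovery`` ties the spectrum side together — preprocessing, peak
detection and clustering, rank-sum marker ranking, GA panel selection,
final-model fitting and blind evaluation — under one config and one global
seed. ``run_validation`` runs the clinical side: per-marker ROC, early-stage
subset ROC, logistic marker combination, stage-wise group comparisons, and
Kaplan-Meier survival with ROC-derived dichotomization.

A single global seed fans out to per-stage seeds through a counter-based
derivation (`numpy` SeedSequence with a fixed stage index as spawn key), so
any stage can be rerun in isolation and reproduce its part of the pipeline.
Reports echo every parameter and seed; no stage reads blind-set labels
before its own evaluation step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical_stats, panel_search, peakcall, preprocess, rank_stats, synth
from .exceptions import ParameterError, ValidationError

logger = logging.getLogger("serumpeaks")

#: fixed stage indices for seed derivation (order is part of the contract)
STAGE_INDEX = {"synth": 0, "synth_blind": 1, "ga": 2, "validation": 3, "survival": 4}


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    if stage not in STAGE_INDEX:
        raise ParameterError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PeakcallConfig:
    snr_min: float = peakcall.DEFAULT_SNR_MIN
    min_sep_da: float | None = None  # None -> 0.3% of m/z
    tol_rel: float = peakcall.DEFAULT_TOL_REL
    min_prevalence: float = peakcall.DEFAULT_MIN_PREVALENCE


@dataclass
class RankConfig:
    p_max: float = rank_stats.SHORTLIST_PRESET["p_max"]
    auc_min: float = rank_stats.SHORTLIST_PRESET["auc_min"]
    top_k: int = rank_stats.SHORTLIST_PRESET["top_k"]


@dataclass
class GASettings:
    """GA block of the run config (the seed comes from the global seed)."""

    population_size: int = 50
    n_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism_count: int = 2
    max_panel_size: int = 10
    fitness_floor: float = 0.5


@dataclass
class RunConfig:
    """Nested configuration for a full discovery + validation run."""

    random_seed: int = 0
    out_dir: str | None = None
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    peakcall: PeakcallConfig = field(default_factory=PeakcallConfig)
    rank: RankConfig = field(default_factory=RankConfig)
    ga: GASettings = field(default_factory=GASettings)
    svm: panel_search.SVMParams = field(default_factory=panel_search.SVMParams)
    synth: synth.SyntheticCohortConfig = field(
        default_factory=synth.SyntheticCohortConfig
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (
            ("preprocess", preprocess.PreprocessConfig),
            ("peakcall", PeakcallConfig),
            ("rank", RankConfig),
            ("ga", GASettings),
            ("svm", panel_search.SVMParams),
            ("synth", synth.SyntheticCohortConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def _matrix_from_spectra(
    spectra, manifest, config: RunConfig, tic_target: float | None = None
) -> tuple[peakcall.PeakMatrix, float]:
    processed, target = preprocess.preprocess_cohort(
        spectra, config.preprocess, tic_target=tic_target
    )
    peaks = []
    for s in processed:
        peaks.extend(
            peakcall.detect_peaks(s, config.peakcall.snr_min, config.peakcall.min_sep_da)
        )
    groups = dict(zip(manifest["sample_id"], manifest["group"]))
    sample_order = [s.sample_id for s in spectra]
    matrix = peakcall.cluster_peaks(
        peaks,
        tol_rel=config.peakcall.tol_rel,
        min_prevalence=config.peakcall.min_prevalence,
        samples=sample_order,
        groups=groups,
    )
    return matrix, target


def _confusion_table_rows(summary: panel_search.ConfusionSummary) -> list[dict]:
    """Confusion counts in the published table layout (one row per group)."""
    sens, spec, _ = panel_search.confusion_metrics(
        summary.tp, summary.fn, summary.tn, summary.fp
    )
    return [
        {
            "group": "HC",
            "total": summary.negatives,
            "correct": summary.tn,
            "misjudged": summary.fp,
            "sensitivity_pct": None,
            "specificity_pct": spec,
        },
        {
            "group": "CRC",
            "total": summary.positives,
            "correct": summary.tp,
            "misjudged": summary.fn,
            "sensitivity_pct": sens,
            "specificity_pct": None,
        },
    ]


def run_discovery(
    config: RunConfig,
    train_spectra,
    train_manifest: pd.DataFrame,
    test_spectra,
    test_manifest: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> dict:
    """Full discovery pipeline; returns (and optionally writes) the report.

    Train and blind sample ids must be disjoint (leakage guard). The blind
    matrix is built and predicted before its labels are consulted.
    """
    train_ids = set(train_manifest["sample_id"])
    test_ids = set(test_manifest["sample_id"])
    overlap = train_ids & test_ids
    if overlap:
        raise ValidationError(
            f"train/test sample ids overlap: {sorted(overlap)[:5]} ..."
        )
    if set(train_manifest["group"]) != {"HC", "CRC"}:
        raise ParameterError("training manifest must contain both HC and CRC samples")

    logger.info("discovery: preprocessing %d training spectra", len(train_spectra))
    train_matrix, tic_target = _matrix_from_spectra(train_spectra, train_manifest, config)
    logger.info("discovery: %d peak clusters in training matrix", train_matrix.n_clusters)

    stats = rank_stats.wilcoxon_rank_markers(train_matrix)
    candidates = rank_stats.filter_candidates(
        stats, config.rank.p_max, config.rank.auc_min, config.rank.top_k
    )
    if not candidates:
        raise ParameterError("no candidate markers pass the shortlist filters")

    ga_cfg = panel_search.GAConfig(
        random_seed=derive_seed(config.random_seed, "ga"),
        population_size=config.ga.population_size,
        n_generations=config.ga.n_generations,
        crossover_rate=config.ga.crossover_rate,
        mutation_rate=config.ga.mutation_rate,
        elitism_count=config.ga.elitism_count,
        max_panel_size=config.ga.max_panel_size,
        fitness_floor=config.ga.fitness_floor,
    )
    panel = panel_search.ga_select(train_matrix, candidates, ga_cfg, config.svm)
    model = panel_search.fit_final(train_matrix, panel)

    # blind spectra are normalized to the training TIC target: evaluation
    # derives nothing from the test cohort
    test_matrix, _ = _matrix_from_spectra(
        test_spectra, test_manifest, config, tic_target=tic_target
    )
    blind = panel_search.blind_test(model, test_matrix)
    panel.blind_result = blind

    report = {
        "config": config.to_dict(),
        "seeds": {"global": config.random_seed, "ga": ga_cfg.random_seed},
        "n_train": {"HC": int((train_manifest["group"] == "HC").sum()),
                    "CRC": int((train_manifest["group"] == "CRC").sum())},
        "n_test": {"HC": int((test_manifest["group"] == "HC").sum()),
                   "CRC": int((test_manifest["group"] == "CRC").sum())},
        "n_clusters": train_matrix.n_clusters,
        "markers": rank_stats.markers_to_dataframe(stats).to_dict(orient="records"),
        "candidates_mz": [c.cluster_mz for c in candidates],
        "panel": panel.as_dict(),
        "model_config_hash": model.config_hash,
        "loocv_table": _confusion_table_rows(panel.loocv_result),
        "blind_table": _confusion_table_rows(blind),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "discovery_report.json").write_text(
            json.dumps(report, indent=1, default=_json_default)
        )
        (out_dir / "discovery_report.md").write_text(_discovery_markdown(report))
        config.to_yaml(out_dir / "run_config.yaml")
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _confusion_md(rows: list[dict]) -> str:
    lines = [
        "| Group | Total | Correct | Misjudged | Sensitivity (%) | Specificity (%) |",
        "|---|---|---|---|---|---|",
    ]
    for r in rows:
        sens = "" if r["sensitivity_pct"] is None else f"{r['sensitivity_pct']}"
        spec = "" if r["specificity_pct"] is None else f"{r['specificity_pct']}"
        lines.append(
            f"| {r['group']} | {r['total']} | {r['correct']} | {r['misjudged']} "
            f"| {sens} | {spec} |"
        )
    return "\n".join(lines)


def _discovery_markdown(report: dict) -> str:
    p = report["panel"]
    members = ", ".join(f"{m:.0f}" for m in p["member_mz"])
    return "\n".join(
        [
            "# Discovery report",
            "",
            f"Global seed: {report['seeds']['global']} (GA seed {report['seeds']['ga']})",
            f"Peak clusters in training matrix: {report['n_clusters']}",
            f"Candidate markers: {len(report['candidates_mz'])}",
            f"Selected panel ({len(p['member_mz'])} markers, Da): {members}",
            f"LOOCV Youden index: {p['youden']:.3f}",
            "",
            "## Training (leave-one-out cross-validation)",
            "",
            _confusion_md(report["loocv_table"]),
            "",
            "## Blind test",
            "",
            _confusion_md(report["blind_table"]),
            "",
        ]
    )


def synthetic_discovery_run(
    config: RunConfig,
    n_hc_train: int = 63,
    n_crc_train: int = 89,
) -> dict:
    """Generate a synthetic cohort, split it, and run the discovery pipeline.

    The cohort comes from ``config.synth`` with its seed derived from the
    global seed; the first ``n_hc_train``/``n_crc_train`` samples per group
    form the training set and the remainder the blind set. The report gains
    ground-truth recovery counts (planted masses recovered by the panel,
    noise clusters selected), which only a synthetic run can provide.
    """
    cfg = dataclasses.replace(config)
    cfg.synth = dataclasses.replace(
        config.synth, random_seed=derive_seed(config.random_seed, "synth")
    )
    spectra, manifest, truth = synth.generate_spectra(cfg.synth)
    train, m_train, test, m_test = synth.split_cohort(
        spectra, manifest, n_hc_train, n_crc_train
    )
    report = run_discovery(cfg, train, m_train, test, m_test)
    panel_mz = report["panel"]["member_mz"]
    tol = cfg.peakcall.tol_rel
    report["truth"] = {
        "n_planted": len(truth.planted_mz()),
        "recovered_planted": truth.count_recovered(panel_mz, tol),
        "noise_in_panel": truth.count_noise(panel_mz, tol),
    }
    return report


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

EARLY_STAGES = ("I", "II")


def run_validation(
    config: RunConfig,
    clinical: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Clinical validation: ROC per marker, combination, stage stats, survival."""
    required = {"group", "mst1", "cea", "fobt"}
    missing = required - set(clinical.columns)
    if missing:
        raise ParameterError(f"clinical table lacks columns: {sorted(missing)}")
    if clinical.empty:
        raise ParameterError("clinical table is empty")

    y = (clinical["group"] == "CRC").astype(int).to_numpy()
    mst1 = clinical["mst1"].to_numpy(dtype=float)
    cea = clinical["cea"].to_numpy(dtype=float)

    # MST1 is lower in CRC; CEA is higher
    roc_mst1 = clinical_stats.roc_analysis(mst1, y, positive_high=False)
    roc_cea = clinical_stats.roc_analysis(cea, y, positive_high=True)

    early = clinical["group"].eq("HC") | clinical["stage"].isin(EARLY_STAGES)
    sub = clinical[early]
    y_early = (sub["group"] == "CRC").astype(int).to_numpy()
    roc_mst1_early = clinical_stats.roc_analysis(
        sub["mst1"].to_numpy(dtype=float), y_early, positive_high=False
    )
    roc_cea_early = clinical_stats.roc_analysis(
        sub["cea"].to_numpy(dtype=float), y_early, positive_high=True
    )

    features = pd.DataFrame(
        {
            # orient MST1 so the combined logistic score increases with risk
            "mst1": -clinical["mst1"].astype(float),
            "cea": np.log1p(clinical["cea"].astype(float)),  # right-skewed
            "fobt": clinical["fobt"].astype(float),
        }
    )
    _, roc_comb = clinical_stats.combine_markers(features, y, binary_cols=["fobt"])

    t_stat, t_p = clinical_stats.group_compare(mst1, clinical["group"], "t_test")
    crc = clinical[clinical["group"] == "CRC"]
    stage_rows = crc[crc["stage"].notna()]
    anova = None
    if stage_rows["stage"].nunique() >= 2:
        f_stat, f_p = clinical_stats.group_compare(
            stage_rows["mst1"].to_numpy(dtype=float), stage_rows["stage"], "anova"
        )
        anova = {"f_statistic": f_stat, "p": f_p}
    late = None
    if {"IV"} <= set(stage_rows["stage"]) and stage_rows["stage"].ne("IV").sum() >= 2:
        lbl = np.where(stage_rows["stage"] == "IV", "IV", "I-III")
        lt, lp = clinical_stats.group_compare(
            stage_rows["mst1"].to_numpy(dtype=float), lbl, "t_test"
        )
        late = {"t_statistic": lt, "p": lp}

    report = {
        "config": config.to_dict(),
        "n": {"HC": int((clinical["group"] == "HC").sum()),
              "CRC": int((clinical["group"] == "CRC").sum())},
        "roc_table": {
            "MST1 in CRC vs HC": roc_mst1.as_dict(),
            "CEA in CRC vs HC": roc_cea.as_dict(),
            "MST1 in early stage CRC vs HC": roc_mst1_early.as_dict(),
            "CEA in early stage CRC vs HC": roc_cea_early.as_dict(),
            "MST1 + CEA + FOBT (logistic)": roc_comb.as_dict(),
        },
        "group_tests": {
            "mst1_hc_vs_crc_t": {"t_statistic": t_stat, "p": t_p},
            "mst1_stage_anova": anova,
            "mst1_stage_iv_vs_i_iii_t": late,
        },
        "survival": None,
    }

    if survival is not None and len(survival):
        for col in ("expression", "time", "event"):
            if col not in survival.columns:
                raise ParameterError(f"survival table lacks column {col!r}")
        cutoff, groups = clinical_stats.dichotomize_by_outcome_roc(
            survival["expression"].to_numpy(dtype=float),
            survival["event"].to_numpy(dtype=int),
        )
        records = survival.assign(group=groups)
        _, chi2, p = clinical_stats.km_logrank(records)
        report["survival"] = {
            "cutoff": cutoff,
            "n_high": int((groups == "high").sum()),
            "n_low": int((groups == "low").sum()),
            "logrank_chi2": chi2,
            "logrank_p": p,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "validation_report.json").write_text(
            json.dumps(report, indent=1, default=_json_default)
        )
        (out_dir / "validation_report.md").write_text(_validation_markdown(report))
    return report


def _validation_markdown(report: dict) -> str:
    lines = [
        "# Validation report",
        "",
        "| Comparison | AUC (95% CI) | Sensitivity (%) | Specificity (%) |",
        "|---|---|---|---|",
    ]
    for name, roc in report["roc_table"].items():
        lo, hi = roc["auc_ci_95"]
        lines.append(
            f"| {name} | {roc['auc']:.3f} ({lo:.3f}-{hi:.3f}) "
            f"| {roc['sensitivity_pct']} | {roc['specificity_pct']} |"
        )
    surv = report["survival"]
    if surv:
        lines += [
            "",
            "## Survival",
            "",
            f"Youden cutoff {surv['cutoff']:.3f}: {surv['n_high']} high / "
            f"{surv['n_low']} low; log-rank chi2 = {surv['logrank_chi2']:.3f}, "
            f"p = {surv['logrank_p']:.2g}",
        ]
    lines.append("")
    return "\n".join(lines)
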