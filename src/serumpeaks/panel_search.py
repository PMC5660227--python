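"""Genetic-algorithm search over peak-cluster subsets scored by RBF-SVM
leave-one-out cross-validation, panel selection by maximal Youden's index,
final model fitting, and blind-set evaluation.

Chromosomes are bit-vectors over the candidate markers with at most
``max_panel_size`` bits set. Fitness is the LOOCV Youden index
(J = sensitivity + specificity - 1); ties are broken towards fewer members,
then lower summed candidate p-value. Uniform crossover, per-bit mutation and
elitism drive the search; the best panel ever evaluated is returned, and the
per-generation best-fitness trajectory is non-decreasing by construction.

Inside every LOOCV fold the features of the n-1 retained samples are
log1p-transformed and z-scored before the SVM is fit — intensity
distributions are strongly right-skewed and the RBF kernel is
scale-sensitive — and the held-out sample is transformed with the fold's
parameters, so no information leaks from the held-out case. Blind-set
evaluation reuses the full-training-set transform and never refits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.svm import SVC

from .exceptions import ParameterError, ValidationError
from .peakcall import DEFAULT_TOL_REL, PeakMatrix
from .rank_stats import MarkerStats

logger = logging.getLogger(__name__)

POSITIVE_GROUP = "CRC"  # positives for sensitivity
NEGATIVE_GROUP = "HC"


@dataclass
class SVMParams:
    """RBF-kernel SVM hyperparameters (the kernel itself is fixed).

    Class weights default to "balanced": the selection objective is Youden's
    J, which costs sensitivity and specificity equally, so the classifier
    must not lean towards the majority class of an unbalanced cohort.
    """

    C: float = 1.0
    gamma: str | float = "scale"  # "scale" = 1 / (n_features * Var(X))
    kernel: str = "rbf"
    class_weight: str | None = "balanced"

    def __post_init__(self):
        if self.kernel != "rbf":
            raise ParameterError("only the RBF kernel is supported")
        if self.C <= 0:
            raise ParameterError("C must be > 0")


@dataclass
class GAConfig:
    """Genetic-algorithm settings; the seed is mandatory for reproducibility."""

    random_seed: int
    population_size: int = 50
    n_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism_count: int = 2
    max_panel_size: int = 10
    fitness_floor: float = 0.5  # best-J below this flags the panel

    def __post_init__(self):
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if self.max_panel_size < 1:
            raise ParameterError("max_panel_size must be >= 1")
        if not 0 <= self.elitism_count <= self.population_size:
            raise ParameterError("elitism_count must be in [0, population_size]")


@dataclass
class ConfusionSummary:
    """Binary confusion counts with the derived Table-style rates."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float | None:
        return self.tp / self.positives if self.positives else None

    @property
    def specificity(self) -> float | None:
        return self.tn / self.negatives if self.negatives else None

    @property
    def youden(self) -> float:
        sens = self.sensitivity or 0.0
        spec = self.specificity or 0.0
        return sens + spec - 1.0

    def as_dict(self) -> dict:
        sens_pct, spec_pct, acc = confusion_metrics(self.tp, self.fn, self.tn, self.fp)
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity_pct": sens_pct,
            "specificity_pct": spec_pct,
            "accuracy_by_group_pct": acc,
            "youden": self.youden,
        }


def _round1_half_up(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int):
    """Percent sensitivity/specificity/per-group accuracy, half-up to 1 decimal.

    Matches the display convention of published confusion tables (e.g.
    88/89 -> 98.9). A zero denominator yields ``None`` (explicitly
    undefined), never 0. Unrounded values are available from
    :class:`ConfusionSummary` directly.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValidationError("confusion counts must be >= 0")
    pos, neg = tp + fn, tn + fp
    sens = _round1_half_up(Decimal(tp * 100) / Decimal(pos)) if pos else None
    spec = _round1_half_up(Decimal(tn * 100) / Decimal(neg)) if neg else None
    acc = {POSITIVE_GROUP: sens, NEGATIVE_GROUP: spec}
    return sens, spec, acc


@dataclass
class Panel:
    """A selected peak-cluster subset with its classifier settings and scores."""

    member_mz: list
    svm_params: SVMParams
    loocv_result: ConfusionSummary
    youden: float
    ga_config: GAConfig | None = None
    low_fitness_flag: bool = False
    fitness_trajectory: list = field(default_factory=list)
    blind_result: ConfusionSummary | None = None

    def as_dict(self) -> dict:
        return {
            "member_mz": [float(m) for m in self.member_mz],
            "svm_params": {"kernel": self.svm_params.kernel, "C": self.svm_params.C,
                           "gamma": self.svm_params.gamma,
                           "class_weight": self.svm_params.class_weight},
            "youden": self.youden,
            "low_fitness_flag": self.low_fitness_flag,
            "loocv": self.loocv_result.as_dict(),
            "blind": self.blind_result.as_dict() if self.blind_result else None,
            "ga_config": None if self.ga_config is None else vars(self.ga_config),
            "fitness_trajectory": list(self.fitness_trajectory),
        }


# ---------------------------------------------------------------------------
# LOOCV scoring
# ---------------------------------------------------------------------------


def _labels_and_features(m: PeakMatrix, members) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(m.groups)
    known = np.isin(groups, (NEGATIVE_GROUP, POSITIVE_GROUP))
    if not known.all():
        raise ValidationError("matrix contains samples with unknown group labels")
    idx = [m.column(mz) for mz in members]
    X = np.log1p(m.values[:, idx])
    y = (groups == POSITIVE_GROUP).astype(int)
    return X, y


def loocv_evaluate(
    m: PeakMatrix, members, svm_params: SVMParams = SVMParams()
) -> ConfusionSummary:
    """Leave-one-out cross-validation of an RBF SVM on a marker subset.

    Each sample is predicted by a model fit on the other n-1 samples, with
    log1p + z-score standardization recomputed on those n-1 samples only.
    Features with zero variance in a training fold are dropped for that fold.
    Deterministic given (matrix, members, svm_params).
    """
    if len(members) == 0:
        raise ParameterError("members must be non-empty")
    X, y = _labels_and_features(m, members)
    n = len(y)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ParameterError("each group needs >= 2 samples for LOOCV")
    tp = fn = tn = fp = 0
    dropped_folds = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        mu = Xt.mean(axis=0)
        sd = Xt.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped_folds += 1
        if not keep.any():
            pred = int(yt.mean() >= 0.5)  # no usable feature: majority class
        else:
            Z = (Xt[:, keep] - mu[keep]) / sd[keep]
            clf = SVC(C=svm_params.C, gamma=svm_params.gamma, kernel="rbf",
                      class_weight=svm_params.class_weight)
            clf.fit(Z, yt)
            z_i = (X[i, keep] - mu[keep]) / sd[keep]
            pred = int(clf.predict(z_i[None, :])[0])
        mask[i] = True
        if y[i] == 1:
            tp += pred
            fn += 1 - pred
        else:
            tn += 1 - pred
            fp += pred
    if dropped_folds:
        logger.debug(
            "LOOCV dropped zero-variance features in %d/%d folds", dropped_folds, n
        )
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _fitness_key(J: float, chrom: np.ndarray, p_values: np.ndarray):
    """Lexicographic fitness: maximize J, then fewer members, then lower
    summed p; a final preference for low-index members makes the argmax
    unique when small-sample p-values tie exactly."""
    members = tuple(-i for i in np.flatnonzero(chrom))
    return (
        J,
        -int(chrom.sum()),
        -float(p_values[chrom.astype(bool)].sum()),
        members,
    )


def _repair(chrom: np.ndarray, max_size: int, rng: np.random.Generator) -> np.ndarray:
    on = np.flatnonzero(chrom)
    if len(on) > max_size:
        off = rng.choice(on, size=len(on) - max_size, replace=False)
        chrom = chrom.copy()
        chrom[off] = 0
    elif len(on) == 0:
        chrom = chrom.copy()
        chrom[rng.integers(len(chrom))] = 1
    return chrom


def ga_select(
    m: PeakMatrix,
    candidates: list[MarkerStats],
    cfg: GAConfig,
    svm_params: SVMParams = SVMParams(),
) -> Panel:
    """Select the marker panel maximizing the LOOCV Youden index by GA.

    Returns the best panel ever evaluated. Fully reproducible from
    ``cfg.random_seed``; repeated chromosomes hit a fitness memo so the cost
    scales with the number of distinct subsets explored.
    """
    if not candidates:
        raise ParameterError("candidate list is empty")
    n_cand = len(candidates)
    p_values = np.array([c.p_value for c in candidates])
    member_mz = [c.cluster_mz for c in candidates]
    rng = np.random.default_rng(cfg.random_seed)
    max_size = min(cfg.max_panel_size, n_cand)

    memo: dict[bytes, tuple] = {}

    def evaluate(chrom: np.ndarray):
        key = chrom.tobytes()
        if key not in memo:
            members = [member_mz[i] for i in np.flatnonzero(chrom)]
            summary = loocv_evaluate(m, members, svm_params)
            memo[key] = (_fitness_key(summary.youden, chrom, p_values), summary)
        return memo[key]

    # initial population: p-ranked prefixes (the strongest k markers for
    # each k — a standard warm start that also seeds the tie-break-preferred
    # family), topped up with random subsets of spread-out sizes
    pop = np.zeros((cfg.population_size, n_cand), dtype=np.int8)
    by_p = np.argsort(p_values, kind="stable")
    n_prefix = min(max_size, cfg.population_size)
    for r in range(n_prefix):
        pop[r, by_p[: r + 1]] = 1
    for r in range(n_prefix, cfg.population_size):
        k = int(rng.integers(1, max_size + 1))
        pop[r, rng.choice(n_cand, size=k, replace=False)] = 1

    best_key, best_chrom, best_summary = None, None, None
    trajectory: list[float] = []

    for gen in range(cfg.n_generations):
        scored = [evaluate(c) for c in pop]
        keys = [s[0] for s in scored]
        order = sorted(range(len(pop)), key=lambda i: keys[i], reverse=True)
        gen_best = order[0]
        if best_key is None or keys[gen_best] > best_key:
            best_key = keys[gen_best]
            best_chrom = pop[gen_best].copy()
            best_summary = scored[gen_best][1]
        trajectory.append(best_key[0])

        # elites survive unchanged
        next_pop = [pop[i].copy() for i in order[: cfg.elitism_count]]
        while len(next_pop) < cfg.population_size:
            # tournament-2 selection
            pa, pb = rng.integers(cfg.population_size, size=2)
            parent1 = pop[pa] if keys[pa] >= keys[pb] else pop[pb]
            pa, pb = rng.integers(cfg.population_size, size=2)
            parent2 = pop[pa] if keys[pa] >= keys[pb] else pop[pb]
            if rng.random() < cfg.crossover_rate:
                take = rng.random(n_cand) < 0.5  # uniform crossover
                child = np.where(take, parent1, parent2)
            else:
                child = parent1.copy()
            flip = rng.random(n_cand) < cfg.mutation_rate
            child = np.where(flip, 1 - child, child).astype(np.int8)
            next_pop.append(_repair(child, max_size, rng))
        pop = np.array(next_pop, dtype=np.int8)

    assert all(b >= a for a, b in zip(trajectory, trajectory[1:])), (
        "elitism violated: best fitness decreased"
    )
    members = [member_mz[i] for i in np.flatnonzero(best_chrom)]
    flagged = best_summary.youden < cfg.fitness_floor
    if flagged:
        logger.warning(
            "best panel Youden %.3f below floor %.2f: no reliable signal",
            best_summary.youden,
            cfg.fitness_floor,
        )
    return Panel(
        member_mz=members,
        svm_params=svm_params,
        loocv_result=best_summary,
        youden=best_summary.youden,
        ga_config=cfg,
        low_fitness_flag=flagged,
        fitness_trajectory=trajectory,
    )


def exhaustive_select(
    m: PeakMatrix,
    candidates: list[MarkerStats],
    max_panel_size: int | None = None,
    svm_params: SVMParams = SVMParams(),
) -> Panel:
    """Exhaustive search over all non-empty candidate subsets.

    Same fitness and tie-break rules as :func:`ga_select`; practical only for
    small candidate lists and used as the GA's independent cross-check.
    """
    if not candidates:
        raise ParameterError("candidate list is empty")
    n_cand = len(candidates)
    if n_cand > 16:
        raise ParameterError("exhaustive search is limited to <= 16 candidates")
    p_values = np.array([c.p_value for c in candidates])
    member_mz = [c.cluster_mz for c in candidates]
    max_size = min(max_panel_size or n_cand, n_cand)
    best_key, best_chrom, best_summary = None, None, None
    for code in range(1, 1 << n_cand):
        chrom = np.array([(code >> i) & 1 for i in range(n_cand)], dtype=np.int8)
        if chrom.sum() > max_size:
            continue
        members = [member_mz[i] for i in np.flatnonzero(chrom)]
        summary = loocv_evaluate(m, members, svm_params)
        key = _fitness_key(summary.youden, chrom, p_values)
        if best_key is None or key > best_key:
            best_key, best_chrom, best_summary = key, chrom, summary
    members = [member_mz[i] for i in np.flatnonzero(best_chrom)]
    return Panel(
        member_mz=members,
        svm_params=svm_params,
        loocv_result=best_summary,
        youden=best_summary.youden,
    )


# ---------------------------------------------------------------------------
# Final model and blind evaluation
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Standardization parameters + SVM fitted on the full training matrix."""

    member_mz: list
    mean_: np.ndarray
    std_: np.ndarray
    classifier: SVC
    svm_params: SVMParams
    config_hash: str
    tol_rel: float = DEFAULT_TOL_REL

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        return (np.log1p(X_raw) - self.mean_) / self.std_

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return self.classifier.predict(self.transform(X_raw))

    def decision_function(self, X_raw: np.ndarray) -> np.ndarray:
        return self.classifier.decision_function(self.transform(X_raw))


def fit_final(m: PeakMatrix, panel: Panel) -> FittedModel:
    """Fit the final panel SVM on the whole training matrix."""
    try:
        X, y = _labels_and_features(m, panel.member_mz)
    except KeyError as exc:
        raise ParameterError(f"panel member absent from training matrix: {exc}") from exc
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ParameterError("zero-variance panel member on the full training set")
    clf = SVC(C=panel.svm_params.C, gamma=panel.svm_params.gamma, kernel="rbf",
              class_weight=panel.svm_params.class_weight)
    clf.fit((X - mu) / sd, y)
    cfg = {
        "member_mz": [float(v) for v in panel.member_mz],
        "C": panel.svm_params.C,
        "gamma": panel.svm_params.gamma,
    }
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return FittedModel(
        member_mz=list(panel.member_mz),
        mean_=mu,
        std_=sd,
        classifier=clf,
        svm_params=panel.svm_params,
        config_hash=digest,
    )


def blind_test(model: FittedModel, test: PeakMatrix) -> ConfusionSummary:
    """Evaluate the trained panel model on an independent test matrix.

    Panel members are matched to test clusters by m/z within the clustering
    tolerance. The model's stored standardization is applied unchanged — no
    refit, no re-standardization — and test labels enter only at scoring.
    """
    if test.n_samples == 0 or test.n_clusters == 0:
        raise ParameterError("test matrix is empty")
    missing = []
    idx = []
    for mz in model.member_mz:
        try:
            idx.append(test.column(mz, model.tol_rel))
        except KeyError:
            missing.append(float(mz))
    if missing:
        raise ParameterError(
            f"test matrix lacks clusters for panel members at m/z {missing}"
        )
    X_raw = test.values[:, idx]
    predictions = model.predict(X_raw)  # labels not consulted
    groups = np.asarray(test.groups)
    known = np.isin(groups, (NEGATIVE_GROUP, POSITIVE_GROUP))
    if not known.all():
        raise ValidationError("test matrix contains samples with unknown group labels")
    y = (groups == POSITIVE_GROUP).astype(int)
    tp = int(((predictions == 1) & (y == 1)).sum())
    fn = int(((predictions == 0) & (y == 1)).sum())
    tn = int(((predictions == 0) & (y == 0)).sum())
    fp = int(((predictions == 1) & (y == 0)).sum())
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)
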