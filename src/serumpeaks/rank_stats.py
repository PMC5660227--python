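"""Cluster ranking: two-group Wilcoxon rank-sum tests, per-marker AUC and
direction, and the candidate filters used to shortlist markers.

Tests are two-sided throughout. For small samples (min group size <= 8)
without ties the exact rank-sum distribution is used; otherwise the normal
approximation with tie and continuity corrections. Per-marker AUC is the
Mann-Whitney statistic U/(n1*n2) with ties counted 0.5, oriented so
AUC >= 0.5; the direction records which group has the larger mean normalized
intensity.

Raw p-values are ranked (no multiple-testing correction is applied to the
selection itself); a Benjamini-Hochberg q-value column is carried along for
information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ValidationError
from .peakcall import PeakMatrix

logger = logging.getLogger(__name__)

UP = "up_in_CRC"
DOWN = "down_in_CRC"

#: discovery-stage default p threshold
P_MAX_DISCOVERY = 0.01
#: candidate-shortlist preset: top-scored peaks entering the panel search
SHORTLIST_PRESET = {"p_max": 1e-5, "auc_min": 0.78, "top_k": 10}


@dataclass
class MarkerStats:
    """Per-cluster two-group statistics."""

    cluster_mz: float
    p_value: float
    auc: float
    direction: str
    mean_by_group: dict
    q_value: float | None = None  # BH-adjusted, informational only

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")
        if not 0.5 <= self.auc <= 1:
            raise ValidationError(f"oriented AUC {self.auc} outside [0.5, 1]")
        mh, mc = self.mean_by_group.get("HC"), self.mean_by_group.get("CRC")
        if mh is not None and mc is not None:
            if mc > mh and self.direction != UP or mh > mc and self.direction != DOWN:
                raise ValidationError("direction inconsistent with group means")


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and the AUC of x-scores vs y-scores.

    Exact distribution when min(n1, n2) <= 8 and there are no ties; normal
    approximation with tie and continuity corrections otherwise. The returned
    AUC is P(x > y) + 0.5 P(x = y), *unoriented*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need >= 2 values")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return 1.0, 0.5  # all values identical: no evidence, chance AUC
    method = "exact" if (min(n1, n2) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    auc = float(res.statistic) / (n1 * n2)
    return float(res.pvalue), auc


def wilcoxon_rank_markers(m: PeakMatrix) -> list[MarkerStats]:
    """Rank every cluster of a labelled matrix; returns stats sorted by p.

    Ties in p are broken by larger AUC, then lower cluster m/z, so the output
    order is deterministic.
    """
    groups = np.asarray(m.groups)
    hc = groups == "HC"
    crc = groups == "CRC"
    if hc.sum() < 2 or crc.sum() < 2:
        raise ParameterError(
            f"need >= 2 samples per group, got HC={int(hc.sum())}, CRC={int(crc.sum())}"
        )
    if hc.sum() + crc.sum() < len(groups):
        raise ValidationError("matrix contains samples with unknown group labels")
    stats = []
    pvals = []
    for j, mz in enumerate(m.cluster_mz):
        x_hc = m.values[hc, j]
        x_crc = m.values[crc, j]
        p, auc_hc = rank_sum_test(x_hc, x_crc)
        mean_hc = float(x_hc.mean())
        mean_crc = float(x_crc.mean())
        direction = UP if mean_crc > mean_hc else DOWN
        stats.append(
            MarkerStats(
                cluster_mz=float(mz),
                p_value=p,
                auc=max(auc_hc, 1.0 - auc_hc),
                direction=direction,
                mean_by_group={"HC": mean_hc, "CRC": mean_crc},
            )
        )
        pvals.append(p)
    if stats:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for s, q in zip(stats, qvals):
            s.q_value = float(q)
    stats.sort(key=lambda s: (s.p_value, -s.auc, s.cluster_mz))
    return stats


def filter_candidates(
    stats: list[MarkerStats],
    p_max: float = P_MAX_DISCOVERY,
    auc_min: float = 0.0,
    top_k: int | None = None,
) -> list[MarkerStats]:
    """Retain markers with p < p_max and AUC > auc_min, truncated to top_k by p.

    The shortlist preset used before the panel search is
    ``filter_candidates(stats, **SHORTLIST_PRESET)`` —
    p < 1e-5, AUC > 0.78, at most 10 markers.
    """
    kept = [s for s in stats if s.p_value < p_max and s.auc > auc_min]
    kept.sort(key=lambda s: (s.p_value, -s.auc, s.cluster_mz))
    if top_k is not None:
        kept = kept[: max(top_k, 0)]
    if not kept:
        logger.warning(
            "no markers pass p < %g and AUC > %g; returning empty candidate list",
            p_max,
            auc_min,
        )
    return kept


def markers_to_dataframe(stats: list[MarkerStats]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_mz": [s.cluster_mz for s in stats],
            "p_value": [s.p_value for s in stats],
            "auc": [s.auc for s in stats],
            "direction": [s.direction for s in stats],
            "mean_HC": [s.mean_by_group["HC"] for s in stats],
            "mean_CRC": [s.mean_by_group["CRC"] for s in stats],
            "q_value": [s.q_value for s in stats],
        }
    )
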