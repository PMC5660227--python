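"""SVM-LOOCV scoring, GA subset search, final fit and blind evaluation."""

import numpy as np
import pytest

import serumpeaks as sp
from serumpeaks.exceptions import ParameterError
from serumpeaks.panel_search import confusion_metrics
from serumpeaks.peakcall import PeakMatrix

from conftest import separable_matrix


def _stats_for(matrix, pvals=None):
    stats = sp.wilcoxon_rank_markers(matrix)
    stats.sort(key=lambda s: s.cluster_mz)
    if pvals is not None:
        for s, p in zip(stats, pvals):
            s.p_value = p
    return stats


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,sens,spec",
        [
            (88, 1, 62, 1, 98.9, 98.4),  # training-style counts
            (36, 2, 24, 2, 94.7, 92.3),  # blind-style counts
            (1, 1, 1, 1, 50.0, 50.0),
        ],
    )
    def test_percentages_round_half_up_to_one_decimal(self, tp, fn, tn, fp, sens, spec):
        s, p, acc = confusion_metrics(tp, fn, tn, fp)
        assert (s, p) == (sens, spec)
        assert acc == {"CRC": sens, "HC": spec}

    def test_half_up_rounding_at_boundary(self):
        # 115/126 = 91.2698... -> 91.3; 29/32 = 90.625 -> 90.6 (exact half:
        # 0.625 rounds the hundredths digit up under half-up at 1 decimal)
        sens, _, _ = confusion_metrics(115, 11, 1, 0)
        assert sens == 91.3
        _, spec, _ = confusion_metrics(1, 0, 29, 3)
        assert spec == 90.6

    def test_zero_denominator_is_undefined_not_zero(self):
        sens, spec, _ = confusion_metrics(0, 0, 5, 0)
        assert sens is None
        assert spec == 100.0


class TestLoocv:
    def test_perfectly_separated_feature_scores_perfectly(self):
        m = separable_matrix(n_per_group=10)
        summary = sp.loocv_evaluate(m, [m.cluster_mz[0]])
        assert summary.sensitivity == 1.0
        assert summary.specificity == 1.0
        assert summary.youden == 1.0

    def test_permuted_labels_show_no_optimism(self):
        # MC null: with labels permuted, LOOCV must not report spurious
        # signal. The mean Youden sits at or slightly below chance —
        # leave-one-out is known to be pessimistically biased on small
        # samples (removing a case shifts the training majority against it),
        # so the band is asymmetric around zero.
        m = separable_matrix(n_per_group=10)
        rng = np.random.default_rng(0)
        youdens = []
        for _ in range(50):
            perm = rng.permutation(len(m.samples))
            shuffled = PeakMatrix(
                cluster_mz=m.cluster_mz,
                samples=m.samples,
                groups=[m.groups[i] for i in perm],
                values=m.values,
            )
            youdens.append(sp.loocv_evaluate(shuffled, [m.cluster_mz[0]]).youden)
        mean_j = np.mean(youdens)
        assert mean_j <= 0.15
        assert mean_j >= -0.35

    def test_single_sample_group_rejected(self):
        m = separable_matrix(n_per_group=10)
        bad = PeakMatrix(
            cluster_mz=m.cluster_mz,
            samples=m.samples,
            groups=["HC"] + ["CRC"] * 19,
            values=m.values,
        )
        with pytest.raises(ParameterError):
            sp.loocv_evaluate(bad, [m.cluster_mz[0]])

    def test_deterministic(self):
        m = separable_matrix(n_per_group=8, n_noise=2, seed=3)
        members = list(m.cluster_mz[:2])
        a = sp.loocv_evaluate(m, members)
        b = sp.loocv_evaluate(m, members)
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)


class TestGaSelect:
    def test_finds_planted_discriminator_among_noise(self):
        # 1 perfect + 7 noise features; exhaustive oracle says best J = 1
        # with the planted feature alone
        m = separable_matrix(n_per_group=10, n_noise=7, seed=1)
        stats = _stats_for(m)
        oracle = sp.exhaustive_select(m, stats)
        assert oracle.youden == 1.0
        assert list(oracle.member_mz) == [m.cluster_mz[0]]
        ga = sp.ga_select(
            m, stats, sp.GAConfig(random_seed=5, population_size=20, n_generations=30)
        )
        assert ga.youden == 1.0
        assert m.cluster_mz[0] in ga.member_mz

    def test_duplicated_perfect_features_tie_break_to_one_member(self):
        m0 = separable_matrix(n_per_group=10)
        values = np.column_stack([m0.values[:, 0], m0.values[:, 0] * 2.0])
        m = PeakMatrix(
            cluster_mz=np.array([1000.0, 2000.0]),
            samples=m0.samples,
            groups=m0.groups,
            values=values,
        )
        stats = _stats_for(m, pvals=[1e-9, 1e-9])
        ga = sp.ga_select(
            m, stats, sp.GAConfig(random_seed=2, population_size=10, n_generations=20)
        )
        assert ga.youden == 1.0
        assert len(ga.member_mz) == 1

    def test_all_noise_candidates_flagged(self):
        rng = np.random.default_rng(9)
        m = PeakMatrix(
            cluster_mz=np.array([1000.0, 2000.0, 3000.0]),
            samples=[f"s{i}" for i in range(20)],
            groups=["HC"] * 10 + ["CRC"] * 10,
            values=rng.lognormal(3, 1, (20, 3)),
        )
        stats = _stats_for(m)
        ga = sp.ga_select(
            m, stats, sp.GAConfig(random_seed=3, population_size=10, n_generations=10)
        )
        assert ga.low_fitness_flag  # best J below the 0.5 floor
        assert ga.youden < 0.5

    def test_trajectory_non_decreasing(self):
        m = separable_matrix(n_per_group=8, n_noise=4, seed=6)
        ga = sp.ga_select(
            m, _stats_for(m),
            sp.GAConfig(random_seed=11, population_size=12, n_generations=15),
        )
        traj = ga.fitness_trajectory
        assert all(b >= a for a, b in zip(traj, traj[1:]))

    def test_reproducible_from_seed(self):
        m = separable_matrix(n_per_group=8, n_noise=4, seed=6)
        cfg = sp.GAConfig(random_seed=11, population_size=12, n_generations=10)
        a = sp.ga_select(m, _stats_for(m), cfg)
        b = sp.ga_select(m, _stats_for(m), cfg)
        assert list(a.member_mz) == list(b.member_mz)
        assert a.fitness_trajectory == b.fitness_trajectory

    def test_empty_candidates_rejected(self):
        m = separable_matrix(n_per_group=8)
        with pytest.raises(ParameterError):
            sp.ga_select(m, [], sp.GAConfig(random_seed=1))


class TestFinalModelAndBlind:
    def _panel(self, m):
        stats = _stats_for(m)
        return sp.ga_select(
            m, stats, sp.GAConfig(random_seed=4, population_size=10, n_generations=10)
        )

    def test_refit_reproduces_decision_values(self):
        m = separable_matrix(n_per_group=10, n_noise=2, seed=8)
        panel = self._panel(m)
        a = sp.fit_final(m, panel)
        b = sp.fit_final(m, panel)
        idx = [m.column(mz) for mz in panel.member_mz]
        X = m.values[:, idx]
        np.testing.assert_array_equal(a.decision_function(X), b.decision_function(X))

    def test_training_predictions_separate_perfect_fixture(self):
        m = separable_matrix(n_per_group=10)
        panel = self._panel(m)
        model = sp.fit_final(m, panel)
        summary = sp.blind_test(model, m)  # training matrix reused as input
        assert summary.youden == 1.0

    def test_missing_member_column_is_error(self):
        m = separable_matrix(n_per_group=10, n_noise=1, seed=2)
        panel = self._panel(m)
        other = PeakMatrix(
            cluster_mz=np.array([9000.0]),
            samples=m.samples,
            groups=m.groups,
            values=m.values[:, :1],
        )
        with pytest.raises(ParameterError, match="m/z"):
            sp.blind_test(sp.fit_final(m, panel), other)

    def test_empty_test_matrix_is_error(self):
        m = separable_matrix(n_per_group=10)
        model = sp.fit_final(m, self._panel(m))
        empty = PeakMatrix(
            cluster_mz=m.cluster_mz, samples=[], groups=[],
            values=np.empty((0, len(m.cluster_mz))),
        )
        with pytest.raises(ParameterError):
            sp.blind_test(model, empty)

    def test_member_matched_within_tolerance(self):
        m = separable_matrix(n_per_group=10)
        panel = self._panel(m)
        model = sp.fit_final(m, panel)
        shifted = PeakMatrix(
            cluster_mz=m.cluster_mz * 1.001,  # within the 0.3% tolerance
            samples=m.samples,
            groups=m.groups,
            values=m.values,
        )
        assert sp.blind_test(model, shifted).youden == 1.0
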