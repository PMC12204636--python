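"""Confusion metrics, chance model, ROC/Youden, bootstrap, sweeps, sample size."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from roca.screen_eval import (BinaryConfusion, ChanceModel,
                              SampleSizeSpec, bootstrap_statistic, chance_confusion,
                              confusion_from_predictions, hanley_mcneil_n,
                              hanley_mcneil_variance, mann_whitney_auc,
                              metrics_from_confusion, p_vs_chance, roc_curve,
                              threshold_sweep, youden_threshold)


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion_from_predictions(["positive"] * 4 + ["negative"] * 6,
                                        ["positive"] * 4 + ["negative"] * 6)
        assert (cm.fp, cm.fn) == (0, 0)
        assert (cm.tp, cm.tn) == (4, 6)

    def test_all_positive_predictions(self):
        true = ["positive"] * 3 + ["negative"] * 7
        cm = confusion_from_predictions(["positive"] * 10, true)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (3, 7, 0, 0)

    def test_order_invariance(self):
        pred = ["positive", "negative", "positive", "negative"]
        true = ["positive", "positive", "negative", "negative"]
        perm = [2, 0, 3, 1]
        a = confusion_from_predictions(pred, true)
        b = confusion_from_predictions([pred[i] for i in perm], [true[i] for i in perm])
        assert a == b

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_from_predictions(["positive"], ["positive", "negative"])


class TestMetrics:
    def test_printed_screening_worked_example(self):
        m = metrics_from_confusion(BinaryConfusion(tp=16, fp=10, fn=1, tn=19))
        assert m.sensitivity == pytest.approx(16 / 17)
        assert m.npv == pytest.approx(19 / 20)
        assert m.accuracy == pytest.approx(35 / 46)
        assert m.ppv == pytest.approx(16 / 26)

    def test_identity_matrix_all_ones(self):
        m = metrics_from_confusion(BinaryConfusion(5, 0, 0, 7))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_zero_denominator_flags_missing_value(self):
        m = metrics_from_confusion(BinaryConfusion(tp=0, fp=3, fn=0, tn=5))
        assert math.isnan(m.sensitivity)
        assert m.undefined() == ("sensitivity",)


class TestChanceModel:
    def test_uniform_binary_with_cohort_priors(self):
        cm, m = chance_confusion(ChanceModel.uniform_binary(17 / 46))
        assert m.accuracy == pytest.approx(0.5)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.npv == pytest.approx(29 / 46)
        assert cm.total == pytest.approx(1.0)

    def test_multiclass_uniform_accuracy_is_one_over_k(self):
        names = ("a", "b", "c", "d")
        model = ChanceModel(q={n: 0.25 for n in names}, p={n: 0.25 for n in names})
        assert model.accuracy() == pytest.approx(0.25)

    @pytest.mark.parametrize("q_pos", [0.1, 0.37, 0.5, 0.9])
    @pytest.mark.parametrize("prior", [0.1, 17 / 46, 0.8])
    def test_npv_equals_negative_prior_for_any_q(self, q_pos, prior):
        """Independence makes chance NPV the negative-class prior exactly."""
        model = ChanceModel(q={"positive": q_pos, "negative": 1 - q_pos},
                            p={"positive": prior, "negative": 1 - prior})
        _, m = chance_confusion(model)
        assert m.npv == pytest.approx(1 - prior)
        assert m.ppv == pytest.approx(prior)

    def test_uniform_q_gives_half_accuracy_for_any_prior(self):
        for prior in (0.05, 0.37, 0.66):
            _, m = chance_confusion(ChanceModel.uniform_binary(prior))
            assert m.accuracy == pytest.approx(0.5)

    def test_unnormalized_inputs_rejected(self):
        with pytest.raises(ValueError):
            ChanceModel(q={"positive": 0.6, "negative": 0.6},
                        p={"positive": 0.5, "negative": 0.5})


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([5, 6, 7, 8], [True, True, False, False])
        assert roc.auc == 1.0

    def test_worked_toy_auc(self):
        # pairs: (6,7),(6,8) concordant, (8,7) discordant, (8,8) tie -> 2.5/4
        roc = roc_curve([6, 8, 7, 8], [True, True, False, False])
        assert roc.auc == pytest.approx(0.625)

    def test_all_ties_give_half(self):
        assert roc_curve([5, 5, 5, 5], [True, True, False, False]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 9, 30)
        labels = rng.random(30) < 0.4
        roc = roc_curve(scores, labels)
        sens = [p.sensitivity for p in roc.points]
        fpr = [p.fpr for p in roc.points]
        assert sens == sorted(sens)
        assert fpr == sorted(fpr)

    def test_auc_equals_mann_whitney_on_200_random_instances(self):
        """Trapezoidal AUC == Mann-Whitney concordance, exact to 1e-12."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 200:
            n = int(rng.integers(3, 13))
            scores = rng.integers(0, 9, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auc = roc_curve(scores, labels).auc
            assert abs(auc - mann_whitney_auc(scores, labels)) < 1e-12
            # scipy cross-check: U statistic / (n1*n2), oriented for low=positive
            u = sps.mannwhitneyu(-scores[labels], -scores[~labels],
                                 alternative="two-sided").statistic
            assert abs(auc - u / (labels.sum() * (~labels).sum())) < 1e-12
            # sklearn cross-check on the oriented scores
            assert abs(auc - roc_auc_score(labels, -scores)) < 1e-12
            checked += 1


class TestYouden:
    def test_worked_toy_threshold(self):
        roc = roc_curve([6, 8, 7, 8], [True, True, False, False])
        t, j = youden_threshold(roc)
        assert (t, j) == (6.0, pytest.approx(0.5))

    def test_perfect_curve_j_is_one(self):
        roc = roc_curve([5, 6, 7, 8], [True, True, False, False])
        _, j = youden_threshold(roc)
        assert j == 1.0

    def test_flat_curve_returns_strictest_threshold(self):
        roc = roc_curve([5, 5, 5, 5], [True, True, False, False])
        t, j = youden_threshold(roc)
        assert j == 0.0
        assert t == 5.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 9, n).astype(float)
            labels = rng.random(n) < 0.45
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(scores, labels)
            t, j = youden_threshold(roc)
            brute = max((p.youden_j for p in roc.points), default=0.0)
            assert j == pytest.approx(brute)


class TestBootstrap:
    def test_constant_data_collapses_ci(self):
        res = bootstrap_statistic([2.0] * 20, lambda r: float(np.mean(r)),
                                  n_boot=100, seed=1)
        assert res.ci_low == res.ci_high == 2.0

    def test_seed_reproducibility(self):
        data = list(np.random.default_rng(5).normal(size=30))
        a = bootstrap_statistic(data, lambda r: float(np.mean(r)), n_boot=200, seed=9)
        b = bootstrap_statistic(data, lambda r: float(np.mean(r)), n_boot=200, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_undefined_resamples_are_redrawn_and_counted(self):
        # statistic undefined unless both classes present
        data = [1] * 2 + [0] * 18

        def stat(recs):
            if len(set(recs)) < 2:
                raise ValueError("single class")
            return float(np.mean(recs))

        res = bootstrap_statistic(data, stat, n_boot=50, seed=3)
        assert res.n_redrawn > 0
        assert len(res.samples) == 50

    def test_nominal_coverage_in_nested_simulation(self):
        """95% percentile intervals cover the true mean ~95% of the time."""
        rng = np.random.default_rng(31)
        outer, hits = 500, 0
        for i in range(outer):
            data = list(rng.normal(0.0, 1.0, 200))
            res = bootstrap_statistic(data, lambda r: float(np.mean(r)),
                                      n_boot=400, seed=1000 + i)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert abs(hits / outer - 0.95) <= 0.03


class TestPVsChance:
    def test_statistic_always_above_chance_hits_floor(self):
        cmp_, _ = p_vs_chance([1.0] * 10, lambda r: 1.0, 0.5, n_boot=100, seed=2)
        assert cmp_.at_floor
        assert cmp_.p == 0.0
        assert cmp_.display() == "<0.01"

    def test_statistic_at_chance_gives_p_one(self):
        cmp_, _ = p_vs_chance([1.0] * 10, lambda r: 0.5, 0.5, n_boot=100, seed=2)
        assert cmp_.p == 1.0

    def test_separated_cohort_auc_beats_chance(self):
        from roca.cohort import CohortSpec, closed_form_performance, simulate_cohort
        spec = CohortSpec(n=46, seed=8,
                          task_fail={"cube": (0.02, 0.7), "infinity": (0.02, 0.7),
                                     "clock": (0.02, 0.8)})
        assert closed_form_performance(spec)["auc"] >= 0.9
        df = simulate_cohort(spec)
        records = list(zip(df["score"], df["status"] == "impaired"))

        def auc_stat(recs):
            s = np.array([r[0] for r in recs], dtype=float)
            y = np.array([r[1] for r in recs], dtype=bool)
            return roc_curve(s, y).auc

        cmp_, _ = p_vs_chance(records, auc_stat, 0.5, n_boot=1000, seed=4)
        assert cmp_.at_floor  # p < .001 territory


class TestThresholdSweep:
    @staticmethod
    def _cohort(seed=0, n=60):
        rng = np.random.default_rng(seed)
        impaired = rng.random(n) < 0.4
        scores = np.where(impaired, rng.integers(0, 7, n), rng.integers(5, 9, n))
        return scores, impaired

    def test_matches_brute_force_per_threshold(self):
        scores, impaired = self._cohort(2)
        result = threshold_sweep(scores, impaired, n_boot=10, seed=1)
        for t in range(9):
            pred = ["positive" if s <= t else "negative" for s in scores]
            true = ["positive" if i else "negative" for i in impaired]
            brute = metrics_from_confusion(confusion_from_predictions(pred, true))
            for name, expected in brute.as_dict().items():
                got = result["sweep"][t]["metrics"][name]
                if math.isnan(expected):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected)

    def test_loosest_threshold_everyone_positive(self):
        scores, impaired = self._cohort(3)
        result = threshold_sweep(scores, impaired, n_boot=10, seed=1)
        top = result["sweep"][8]["metrics"]
        assert top["sensitivity"] == 1.0
        assert top["specificity"] == 0.0

    def test_perfectly_separated_cohort(self):
        scores = np.array([0, 0, 0, 8, 8, 8, 8])
        impaired = np.array([True, True, True, False, False, False, False])
        result = threshold_sweep(scores, impaired, n_boot=20, seed=5)
        t = result["best_screen_threshold"]
        assert result["sweep"][t]["metrics"]["sensitivity"] == 1.0
        assert result["sweep"][t]["metrics"]["npv"] == 1.0

    def test_single_status_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([1, 2, 3], [True, True, True])


class TestHanleyMcNeil:
    def test_variance_limit_at_half_single_observation(self):
        assert hanley_mcneil_variance(0.5, 1, 1) == pytest.approx(0.25)

    def test_q_values_at_07(self):
        res = hanley_mcneil_n(SampleSizeSpec(0.7))
        assert res["q1"] == pytest.approx(0.7 / 1.3)
        assert res["q2"] == pytest.approx(0.98 / 1.7)

    def test_required_n_nonincreasing_in_auc(self):
        sizes = [hanley_mcneil_n(SampleSizeSpec(a))["n_per_group"]
                 for a in (0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)]
        assert sizes == sorted(sizes, reverse=True)

    def test_auc_at_or_below_half_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(0.5)
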