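"""Outcome-model machinery against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histopheno import models
from histopheno.models import (
    auroc,
    fisher_combine,
    fit_cox_en,
    fit_logistic_en,
    harrell_c,
    kaplan_meier,
    km_max_gap,
    logrank_test,
    lower_median,
    make_folds,
    stratify_risk,
    uno_c,
    wald_pvalues_logistic,
)


# ---------------------------------------------------------------------------
# oracles (independent of the implementation under test)


def pairwise_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def pairwise_harrell(scores, time, event):
    conc = comp = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or not event[i]:
                continue
            if time[i] < time[j]:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp


def censoring_km(time, event):
    """Product-limit estimate of the censoring distribution G(t)."""
    order = np.argsort(time)
    t, e = np.asarray(time)[order], np.asarray(event)[order]
    uniq = np.unique(t)
    surv, s = [], 1.0
    for u in uniq:
        at_risk = (t >= u).sum()
        d_cens = ((t == u) & (e == 0)).sum()
        s *= 1 - d_cens / at_risk
        surv.append((u, s))
    return surv


def eval_km_left(curve, t):
    """G(t-): left-continuous evaluation of a step function."""
    s = 1.0
    for u, v in curve:
        if u < t:
            s = v
        else:
            break
    return s


def ipcw_uno(scores, time, event, tau):
    curve = censoring_km(time, event)
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        if not event[i] or time[i] >= tau:
            continue
        w = 1.0 / eval_km_left(curve, time[i]) ** 2
        for j in range(n):
            if time[j] > time[i]:
                den += w
                if scores[i] > scores[j]:
                    num += w
                elif scores[i] == scores[j]:
                    num += 0.5 * w
    return num / den


# ---------------------------------------------------------------------------
# metric tests


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([1.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_six_points_with_tie_matches_pair_enumeration(self):
        scores = [0.2, 0.5, 0.5, 0.7, 0.1, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        assert auroc(scores, labels) == pytest.approx(pairwise_auroc(scores, labels), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])


class TestHarrellC:
    def test_perfect_and_reversed_ordering(self):
        time = [1.0, 2.0, 3.0, 4.0]
        event = [1, 1, 1, 1]
        assert harrell_c([4, 3, 2, 1], time, event) == 1.0
        assert harrell_c([1, 2, 3, 4], time, event) == 0.0

    def test_mixed_censoring_fixture_matches_pair_oracle(self, survival_fixture):
        f = survival_fixture
        got = harrell_c(f["score"], f["time"], f["event"])
        want = pairwise_harrell(f["score"].tolist(), f["time"].tolist(), f["event"].tolist())
        assert got == pytest.approx(want, abs=1e-9)

    def test_tied_scores_count_half(self):
        time = [1.0, 2.0, 3.0]
        event = [1, 1, 1]
        scores = [2.0, 2.0, 1.0]
        assert harrell_c(scores, time, event) == pytest.approx(
            pairwise_harrell(scores, time, event), abs=1e-9
        )

    def test_monotone_transform_invariance(self, survival_fixture):
        f = survival_fixture
        base = harrell_c(f["score"], f["time"], f["event"])
        assert harrell_c(np.exp(f["score"]), f["time"], f["event"]) == pytest.approx(base)
        assert harrell_c(3 * f["score"] + 7, f["time"], f["event"]) == pytest.approx(base)


class TestUnoC:
    def test_no_censoring_equals_harrell(self):
        time = [2.0, 4.0, 1.0, 8.0, 5.0]
        event = [1, 1, 1, 1, 1]
        scores = [1.0, 0.5, 2.0, -1.0, 0.0]
        tau = max(time)
        assert uno_c(scores, time, event, tau=tau) == pytest.approx(
            harrell_c(scores, time, event), abs=1e-9
        )

    def test_perfect_ordering(self):
        time = [1.0, 2.0, 3.0, 4.0]
        assert uno_c([4, 3, 2, 1], time, [1, 1, 1, 1], tau=4.0) == 1.0

    def test_ipcw_fixture_matches_formula_oracle(self, survival_fixture):
        f = survival_fixture
        tau = 10.0
        got = uno_c(f["score"], f["time"], f["event"], tau=tau)
        want = ipcw_uno(
            f["score"].tolist(), f["time"].tolist(), f["event"].tolist(), tau
        )
        assert got == pytest.approx(want, abs=1e-6)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        t, s = kaplan_meier([3.0, 5.0, 7.0], [0, 0, 0])
        assert (s == 1.0).all()

    def test_distinct_event_times_closed_form(self):
        n = 5
        t, s = kaplan_meier(np.arange(1.0, n + 1), np.ones(n, int))
        np.testing.assert_allclose(s, [(n - i) / n for i in range(1, n + 1)])

    def test_textbook_interleaved_censoring(self):
        # hand product-limit: events at 1, 3, 5, 6 with censoring at 2+ and 4+
        t, s = kaplan_meier([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
        steps = dict(zip(t, s))
        assert steps[1.0] == pytest.approx(5 / 6)
        assert steps[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert steps[5.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert steps[6.0] == pytest.approx(0.0)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [1, 1, 0, 1, 1, 0]
        group = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank_test(time, event, group)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_death_closed_form(self):
        # one death in group a at t=1 with 2 vs 2 at risk:
        # O-E = 1 - 1/2, V = 1 * (2/4) * (2/4) * (4-1)/(4-1) = 1/4 -> chi2 = 1
        time = [1.0, 5.0, 5.0, 5.0]
        event = [1, 0, 0, 0]
        group = ["a", "a", "b", "b"]
        stat, p = logrank_test(time, event, group)
        assert stat == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(1.0, df=1), abs=1e-9)

    def test_p_matches_chi2_survival_function(self, survival_fixture):
        f = survival_fixture
        group = ["a", "b"] * 4
        stat, p = logrank_test(f["time"], f["event"], group)
        assert p == pytest.approx(stats.chi2.sf(stat, df=1), abs=1e-12)


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        assert fisher_combine([0.123]) == pytest.approx(0.123, abs=1e-12)

    def test_two_p05_matches_chi2_tail(self):
        x = -2 * (np.log(0.05) + np.log(0.05))
        assert fisher_combine([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x, df=4), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


# ---------------------------------------------------------------------------
# fitters


def logit_newton(X, y):
    """Unpenalized logistic MLE + Wald p by direct matrix algebra."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(100):
        p = 1 / (1 + np.exp(-Xd @ beta))
        W = p * (1 - p)
        grad = Xd.T @ (y - p)
        H = Xd.T @ (Xd * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    z = beta / se
    return beta, 2 * stats.norm.sf(np.abs(z))


class TestLogisticEN:
    def test_null_features_shrink_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 6))
        y = rng.integers(0, 2, size=400)
        fit = fit_logistic_en(X, y, alpha=0.5)
        assert np.abs(fit.coef).max() < 0.05

    def test_row_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + rng.normal(0, 0.5, 60) > 0).astype(int)
        f1 = fit_logistic_en(X, y, alpha=0.25)
        f2 = fit_logistic_en(np.vstack([X, X]), np.concatenate([y, y]), alpha=0.25)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_en(np.zeros((4, 2)), np.ones(4), 0.25)

    def test_wald_matches_matrix_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 2))
        y = (0.8 * X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 1, 300) > 0).astype(int)
        fit = fit_logistic_en(X, y, alpha=1e-6)  # essentially unpenalized, all active
        p_impl = wald_pvalues_logistic(fit, X, y)
        _, p_oracle = logit_newton(X, y.astype(float))
        np.testing.assert_allclose(p_impl, p_oracle[1:], atol=1e-6)

    def test_wald_symmetric_in_coefficient_sign(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 1))
        y = (X[:, 0] + rng.normal(0, 1, 200) > 0).astype(int)
        f_pos = fit_logistic_en(X, y, alpha=1e-6)
        f_neg = fit_logistic_en(-X, y, alpha=1e-6)
        p_pos = wald_pvalues_logistic(f_pos, X, y)
        p_neg = wald_pvalues_logistic(f_neg, -X, y)
        np.testing.assert_allclose(p_pos, p_neg, atol=1e-8)


class TestCoxEN:
    def test_rank_invariance_to_time_shift(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        time = rng.exponential(10, 80)
        event = rng.integers(0, 2, 80)
        event[0] = 1
        f1 = fit_cox_en(X, time, event)
        f2 = fit_cox_en(X, time + 100.0, event)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox_en(np.zeros((5, 2)), np.arange(5.0) + 1, np.zeros(5))

    def test_planted_coefficient_recovers_sign(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        hazard = np.exp(1.0 * X[:, 0])
        time = rng.exponential(1 / hazard)
        event = np.ones(200)
        fit = fit_cox_en(X, time, event, alpha=0.05)
        assert fit.coef[0] > 0
        assert abs(fit.coef[0]) > np.abs(fit.coef[1:]).max()


# ---------------------------------------------------------------------------
# folds and risk stratification


class TestFolds:
    def make_patients(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "dfs_months": rng.exponential(30, n).round(2),
                "event": rng.integers(0, 2, n),
            }
        )

    def test_every_patient_in_exactly_one_test_fold(self):
        pat = self.make_patients()
        split = make_folds(pat, seed=1)
        test_sets = [set(split.patients(f, "test")) for f in range(3)]
        all_test = set.union(*test_sets)
        assert all_test == set(pat["patient_id"])
        assert sum(len(s) for s in test_sets) == len(pat)

    def test_train_val_disjoint_within_fold(self):
        split = make_folds(self.make_patients(), seed=2)
        for f in range(3):
            tr = set(split.patients(f, "train"))
            va = set(split.patients(f, "validation"))
            te = set(split.patients(f, "test"))
            assert not (tr & va or tr & te or va & te)
            assert len(va) == pytest.approx(0.2 * (len(tr) + len(va)), abs=1)

    def test_km_gap_constraint_verified_by_recomputation(self):
        pat = self.make_patients(n=120, seed=1)
        split = make_folds(pat, seed=1, km_tolerance=0.15)
        pat_idx = pat.set_index("patient_id")
        for f in range(3):
            tr = pat_idx.loc[split.patients(f, "train")]
            te = pat_idx.loc[split.patients(f, "test")]
            gap = km_max_gap(
                tr["dfs_months"], tr["event"], te["dfs_months"], te["event"]
            )
            assert gap <= 0.15 + 1e-12
            assert gap == pytest.approx(split.km_gaps[f], abs=1e-12)

    def test_infeasible_tolerance_returns_best_split_with_warning(self, caplog):
        import logging

        pat = self.make_patients(n=40, seed=5)
        with caplog.at_level(logging.WARNING):
            split = make_folds(pat, seed=5, km_tolerance=0.0, max_attempts=5)
        assert "no split met" in caplog.text
        assert set.union(*(set(split.patients(f, "test")) for f in range(3))) == set(
            pat["patient_id"]
        )

    def test_identical_survival_accepts_first_split(self):
        pat = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(30)], "dfs_months": 10.0, "event": 1}
        )
        split = make_folds(pat, seed=0, km_tolerance=0.0)
        assert max(split.km_gaps) == 0.0


class TestStratifyRisk:
    def test_lower_median_convention(self):
        assert lower_median([4.0, 1.0, 3.0, 2.0]) == 2.0
        assert lower_median([5.0, 1.0, 3.0]) == 3.0

    def test_translation_shifts_threshold_not_groups(self):
        rng = np.random.default_rng(6)
        train = rng.normal(size=21)
        test = rng.normal(size=20)
        time = rng.exponential(10, 20)
        event = np.ones(20, int)
        g1 = stratify_risk(train, test, time, event)
        g2 = stratify_risk(train + 5.0, test + 5.0, time, event)
        assert g2.threshold == pytest.approx(g1.threshold + 5.0)
        np.testing.assert_array_equal(g1.labels, g2.labels)

    def test_one_sided_scores_skip_logrank(self):
        g = stratify_risk([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [5.0, 6.0, 7.0], [1, 1, 0])
        assert (g.labels == "high").all()
        assert g.logrank_p is None


class TestCrossValidate:
    def test_report_shape_and_mean_coefficient(self, small_cohort):
        from histopheno import composition
        from histopheno.clustering import HPCAssignment

        _, manifest, truth = small_cohort
        tp = truth.tile_phenotype
        assignment = HPCAssignment(
            tp["tile_id"].to_numpy(object), tp["phenotype"].to_numpy(), 0.0
        )
        counts = composition.composition_matrix(assignment, tp, "patient_id", as_counts=True)
        clr = composition.clr_matrix(counts)
        pat = manifest.drop_duplicates("patient_id")
        folds = make_folds(pat, seed=4)
        report = models.cross_validate(
            clr.loc[pat["patient_id"]], pat, folds, "cox", compute_wald=False
        )
        assert len(report.fold_metrics) == 3
        np.testing.assert_allclose(
            report.mean_coef, np.mean([f.coef for f in report.fold_fits], axis=0)
        )
        assert set(report.fold_metrics.columns) == {
            "harrell_c_validation",
            "uno_c_validation",
            "harrell_c_test",
            "uno_c_test",
        }
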