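"""Split, standardisation, screening, pruning, fitting, evaluation."""

import numpy as np
import pandas as pd
import pytest

from rwradiomics.io import CohortRecord, ValidationError
from rwradiomics.modelling import (
    SplitSpec,
    auc_score,
    bootstrap_auc,
    compare_models,
    fit_elastic_net_cv,
    mwu_screen,
    select_optimal_week,
    spearman_prune,
    split_cohort,
    summarise_outcomes,
    youden_operating_point,
    zscore,
)

from conftest import oracle_auc_paircount, oracle_youden


def _cohort(n_pos, n_neg, regimen="74Gy_37F"):
    recs = [CohortRecord(f"P{k:03d}", regimen, 1) for k in range(n_pos)]
    recs += [CohortRecord(f"N{k:03d}", regimen, 0) for k in range(n_neg)]
    return recs


class TestSplit:
    def test_reproduces_printed_74gy_split(self):
        cohort = _cohort(32, 78)  # the 74 Gy group
        train, test = split_cohort(cohort, SplitSpec(seed=0))
        assert (len(train), len(test)) == (82, 28)
        test_pos = sum(1 for p in test if p.startswith("P"))
        assert test_pos == 8 and len(test) - test_pos == 20

    def test_reproduces_printed_60gy_split(self):
        cohort = _cohort(30, 47, regimen="60Gy_20F")
        train, test = split_cohort(cohort, SplitSpec(seed=0))
        assert (len(train), len(test)) == (58, 19)
        test_pos = sum(1 for p in test if p.startswith("P"))
        assert test_pos == 8 and len(test) - test_pos == 11

    def test_deterministic_given_seed(self):
        cohort = _cohort(20, 40)
        a = split_cohort(cohort, SplitSpec(seed=3))
        b = split_cohort(cohort, SplitSpec(seed=3))
        c = split_cohort(cohort, SplitSpec(seed=4))
        assert a == b
        assert a != c

    def test_partition_property(self):
        cohort = _cohort(15, 30)
        train, test = split_cohort(cohort, SplitSpec(seed=1))
        assert sorted(train + test) == sorted(r.patient_id for r in cohort)
        assert not set(train) & set(test)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            split_cohort(_cohort(1, 30), SplitSpec(seed=0))


class TestOutcomeSummary:
    def test_grade_counts_and_ge1_total(self):
        recs = (
            [CohortRecord(f"A{k}", "74Gy_37F", 0) for k in range(5)]
            + [CohortRecord(f"B{k}", "74Gy_37F", 1) for k in range(3)]
            + [CohortRecord(f"C{k}", "74Gy_37F", 2) for k in range(2)]
            + [CohortRecord("D0", "74Gy_37F", 3)]
        )
        out = summarise_outcomes(recs).set_index("endpoint")["n"]
        assert out["G0"] == 5 and out["G1"] == 3
        assert out["G2"] == 2 and out["G3"] == 1
        assert out[">=G1"] == 6


class TestZscore:
    def test_population_sd_convention(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        z, _, params = zscore(train)
        np.testing.assert_allclose(
            z["f"].to_numpy(), [-1.224744871, 0.0, 1.224744871]
        )
        assert params.loc["f", "sd"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_training_columns_standardised(self, rng):
        train = pd.DataFrame(rng.normal(5, 3, size=(40, 6)))
        train.columns = [f"f{k}" for k in range(6)]
        z, _, _ = zscore(train)
        np.testing.assert_allclose(z.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(ddof=0), 1, atol=1e-10)

    def test_constant_column_dropped_with_log(self, rng, caplog):
        train = pd.DataFrame({"good": rng.normal(size=10), "flat": 7.0})
        with caplog.at_level("WARNING"):
            z, _, _ = zscore(train)
        assert list(z.columns) == ["good"]
        assert any("constant" in r.message for r in caplog.records)

    def test_test_value_at_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"f": [2.0]})
        _, tz, _ = zscore(train, test)
        assert tz["f"].iloc[0] == pytest.approx(0.0)


class TestScreen:
    def test_identical_groups_give_p_one(self):
        X = pd.DataFrame({"f": [1.0] * 10})
        y = np.array([0, 1] * 5)
        res = mwu_screen(X, y)
        assert res.pvalue("f") == 1.0

    def test_fully_separated_small_groups_exact_p(self):
        X = pd.DataFrame({"f": [4.0, 5.0, 6.0, 1.0, 2.0, 3.0]})
        y = np.array([1, 1, 1, 0, 0, 0])
        res = mwu_screen(X, y)
        assert res.pvalue("f") == pytest.approx(0.1)  # exact enumeration
        assert res.table.loc[0, "U"] == 9.0  # all 9 pairs favour group 1

    def test_ranked_ascending_with_top10(self, rng):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame(rng.normal(size=(n, 15)),
                         columns=[f"f{k:02d}" for k in range(15)])
        X["strong"] = y + rng.normal(scale=0.2, size=n)
        res = mwu_screen(X, y)
        assert res.table["p"].is_monotonic_increasing
        assert res.table.iloc[0]["feature"] == "strong"
        assert len(res.top(10)) == 10


class TestPrune:
    def test_duplicated_feature_keeps_one(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        a = rng.normal(size=20) + y
        X = pd.DataFrame({"a": a, "a_copy": a, "b": rng.normal(size=20)})
        screen = mwu_screen(X, y)
        pruned = spearman_prune(X, screen)
        assert "b" in pruned.retained
        assert sum(f in pruned.retained for f in ("a", "a_copy")) == 1

    def test_independent_features_all_retained(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 12)),
                         columns=[f"f{k}" for k in range(12)])
        y = np.array([0, 1] * 100)
        pruned = spearman_prune(X, mwu_screen(X, y))
        assert pruned.retained == list(X.columns)

    def test_three_collinear_features_one_survivor(self, rng):
        base = rng.normal(size=50)
        y = (base + rng.normal(scale=0.5, size=50) > 0).astype(int)
        X = pd.DataFrame({
            "x1": base, "x2": base * 2 + 1, "x3": base + rng.normal(scale=1e-6, size=50),
            "noise": rng.normal(size=50),
        })
        pruned = spearman_prune(X, mwu_screen(X, y))
        assert sum(f in pruned.retained for f in ("x1", "x2", "x3")) == 1
        assert "noise" in pruned.retained

    def test_no_retained_pair_reaches_threshold(self, rng):
        # strongly correlated block plus noise; post-hoc invariant
        base = rng.normal(size=(100, 3))
        X = pd.DataFrame(
            np.hstack([base, base @ rng.normal(size=(3, 5)) +
                       0.1 * rng.normal(size=(100, 5))]),
            columns=[f"f{k}" for k in range(8)],
        )
        y = np.array([0, 1] * 50)
        pruned = spearman_prune(X, mwu_screen(X, y), threshold=0.8)
        from scipy import stats

        rho = np.atleast_2d(stats.spearmanr(X[pruned.retained]).statistic)
        off = np.abs(rho[~np.eye(len(pruned.retained), dtype=bool)])
        assert off.size == 0 or off.max() < 0.8


class TestElasticNet:
    def test_full_shrinkage_limit(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{k}" for k in range(5)])
        y = np.array([1] * 20 + [0] * 40)
        fit = fit_elastic_net_cv(X, y, c_grid=np.array([1e-4]), seed=0)
        assert (fit.coef == 0).all()
        assert fit.intercept == pytest.approx(np.log(20 / 40), abs=0.05)

    def test_separable_single_feature_perfect_training_auc(self, rng):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)
        X = pd.DataFrame({"f": x})
        fit = fit_elastic_net_cv(X, y, c_grid=np.array([1e3]), seed=0)
        assert not fit.degenerate
        assert auc_score(y, fit.decision_scores(X)) == 1.0

    def test_informative_features_recovered(self, rng):
        hits = 0
        for rep in range(10):
            n = 200
            X = rng.normal(size=(n, 23))
            beta = np.zeros(23)
            beta[:3] = 1.0  # 3 informative, 20 noise, 1 SD effect
            logits = X @ beta
            y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
            df = pd.DataFrame(X, columns=[f"f{k:02d}" for k in range(23)])
            fit = fit_elastic_net_cv(df, y, seed=rep)
            informative_nonzero = int((fit.coef[:3] != 0).sum())
            hits += informative_nonzero >= 2
        assert hits >= 8

    def test_class_floor_for_cv(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        X.columns = ["a", "b", "c"]
        y = np.array([1] * 3 + [0] * 7)
        with pytest.raises(ValidationError):
            fit_elastic_net_cv(X, y, folds=5)


class TestAuc:
    def test_matches_paircount_oracle_on_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            s = rng.integers(0, 5, size=n).astype(float)  # ties included
            assert auc_score(y, s) == pytest.approx(oracle_auc_paircount(y, s))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.normal(size=50)
        assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s))


class TestBootstrap:
    def test_perfect_scores_degenerate_ci(self):
        y = np.array([0] * 10 + [1] * 10)
        s = y.astype(float)
        auc, ci, samples = bootstrap_auc(s, y, n_boot=50, seed=0)
        assert auc == 1.0 and ci == (1.0, 1.0)
        assert (samples == 1.0).all()

    def test_null_scores_near_half(self, rng):
        ok = 0
        for rep in range(10):
            y = np.array([0] * 100 + [1] * 100)
            s = rng.normal(size=200)
            auc, ci, _ = bootstrap_auc(s, y, n_boot=100, seed=rep)
            ok += 0.4 <= auc <= 0.6
            assert ci[0] <= auc <= ci[1]
        assert ok >= 9

    def test_resamples_preserve_class_balance(self, rng):
        y = np.array([0] * 30 + [1] * 10)
        s = rng.normal(size=40)
        _, _, samples = bootstrap_auc(s, y, n_boot=100, seed=1)
        assert len(samples) == 100
        assert np.isfinite(samples).all()


class TestYouden:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        thr, sen, spe = youden_operating_point(s, y)
        assert sen == 1.0 and spe == 1.0
        assert 0.3 < thr <= 0.8

    def test_identical_scores_give_zero_j(self):
        y = np.array([0, 1, 0, 1])
        s = np.ones(4)
        thr, sen, spe = youden_operating_point(s, y)
        assert sen + spe - 1 == pytest.approx(0.0)

    def test_matches_all_cut_points_oracle(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, size=20)
            y[0], y[1] = 0, 1
            s = np.round(rng.normal(size=20), 1)
            thr, sen, spe = youden_operating_point(s, y)
            othr, osen, ospe = oracle_youden(s, y)
            assert (sen + spe) == pytest.approx(osen + ospe)
            assert thr == pytest.approx(othr)  # ties -> lower threshold


class TestCompareModels:
    def test_identical_sets_give_half(self, rng):
        a = rng.normal(size=100)
        assert compare_models(a, a) == pytest.approx(0.5, abs=0.01)

    def test_shifted_set_strongly_significant(self, rng):
        b = rng.normal(scale=0.01, size=100)
        assert compare_models(b + 0.2, b) < 1e-3

    def test_antisymmetry(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(size=100) + 0.05
        assert compare_models(a, b) + compare_models(b, a) == pytest.approx(
            1.0, abs=1e-6
        )


class TestSelectOptimalWeek:
    def _sweep(self, aucs_by_tp, rng):
        """Construct a SweepResult-like object from bootstrap AUC sets."""
        from rwradiomics.modelling import ModelResult, SweepResult

        models = {}
        for tp, (mu, sd) in aucs_by_tp.items():
            boot = np.clip(rng.normal(mu, sd, size=100), 0, 1)
            models[tp] = ModelResult(
                time_point=tp, mode="separate", n_train=0, n_test=0,
                selection=[], fit=None, coef_pvalues=pd.Series(dtype=float),
                threshold=0.0,
                train_auc=mu, train_ci=(mu - sd, mu + sd), train_boot=boot,
                train_sen=0, train_spe=0,
                test_auc=mu, test_ci=(mu - sd, mu + sd), test_boot=boot,
                test_sen=0, test_spe=0,
            )
        return SweepResult(
            mode="separate", time_points=list(aucs_by_tp), models=models,
            comparisons=pd.DataFrame(), selections={},
        )

    def test_plateau_returns_first_plateau_point(self, rng):
        sweep = self._sweep(
            {"CT": (0.55, 0.02), "W1": (0.65, 0.02), "W2": (0.75, 0.02),
             "W3": (0.85, 0.02), "W4": (0.853, 0.02)}, rng,
        )
        assert select_optimal_week(sweep).time_point == "W3"

    def test_indistinguishable_returns_earliest(self, rng):
        sweep = self._sweep(
            {tp: (0.7, 0.05) for tp in ["CT", "W1", "W2", "W3"]}, rng
        )
        assert select_optimal_week(sweep).time_point == "CT"

    def test_strictly_improving_returns_final_week_annotated(self, rng):
        sweep = self._sweep(
            {"CT": (0.55, 0.01), "W1": (0.65, 0.01), "W2": (0.75, 0.01),
             "W3": (0.85, 0.01), "W4": (0.95, 0.01)}, rng,
        )
        opt = select_optimal_week(sweep)
        assert opt.time_point == "W4"
        assert "limited practical utility" in opt.annotation

    def test_rationale_lists_all_later_comparisons(self, rng):
        sweep = self._sweep(
            {"CT": (0.5, 0.02), "W1": (0.8, 0.02), "W2": (0.8, 0.02)}, rng
        )
        opt = select_optimal_week(sweep)
        assert opt.time_point == "W1"
        assert len(opt.rationale) == 3  # CT-W1, CT-W2, W1-W2
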