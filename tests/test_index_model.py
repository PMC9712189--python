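import numpy as np
import pandas as pd
import pytest

from tcrpi import (
    CompositeIndexModel,
    PairIndexModel,
    ROCCurve,
    assign_risk,
    compute_tcrpi,
    encode_clinical,
    fit_ctcpi,
    fit_final_cox,
    fit_lasso_cox,
    logrank_test,
    select_cutoff,
    select_prognostic_pairs,
    split_cohort,
    time_dependent_roc,
)
from tcrpi.errors import DomainError, SchemaError, UndefinedTestError

from _oracles import (
    auc_u_statistic,
    cox_newton,
    logrank_enumeration,
    univariate_cox_bisection,
)
from conftest import make_surv


class TestSplitCohort:
    def test_meta_cohort_part_sizes(self):
        ids = [f"s{i}" for i in range(3134)]
        parts = split_cohort(ids, seed=0)
        assert sorted(len(p) for p in parts) == [783, 783, 784, 784]

    def test_partition_and_determinism(self):
        ids = [f"s{i}" for i in range(101)]
        parts = split_cohort(ids, seed=9)
        again = split_cohort(ids, seed=9)
        assert parts == again
        flat = [s for p in parts for s in p]
        assert sorted(flat) == sorted(ids) and len(set(flat)) == len(ids)
        assert split_cohort(ids, seed=10) != parts

    def test_too_few_samples(self):
        with pytest.raises(DomainError):
            split_cohort(["a", "b", "c"], seed=0)


class TestLogrank:
    def test_identical_groups_no_separation(self):
        t = np.array([3.0, 5.0, 8.0, 11.0])
        e = np.array([1, 0, 1, 1])
        stat, p = logrank_test(t, e, t.copy(), e.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_risk_set_enumeration_oracle(self):
        ta = np.array([2.0, 5.0, 7.0, 11.0])
        ea = np.array([1, 1, 0, 1])
        tb = np.array([3.0, 6.0, 9.0, 14.0])
        eb = np.array([1, 0, 1, 1])
        stat, p = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_enumeration(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_zero_events_undefined(self):
        t = np.array([1.0, 2.0])
        z = np.zeros(2, dtype=int)
        with pytest.raises(UndefinedTestError):
            logrank_test(t, z, t, z)
        with pytest.raises(UndefinedTestError):
            logrank_test(t, z, np.array([]), np.array([]))


class TestSelectPrognosticPairs:
    def _pm_surv(self, rng, n=60):
        pm = pd.DataFrame(
            rng.integers(0, 2, size=(5, n)),
            index=[f"a|b{k}" for k in range(5)],
            columns=[f"s{i}" for i in range(n)],
        )
        time = pd.Series(rng.exponential(20, n), index=pm.columns)
        event = pd.Series(rng.integers(0, 2, n), index=pm.columns)
        return pm, time, event

    def test_alpha_zero_selects_nothing(self, rng):
        pm, time, event = self._pm_surv(rng)
        assert select_prognostic_pairs(pm, time, event, alpha=0.0) == []

    def test_single_group_pair_skipped(self, rng, caplog):
        pm, time, event = self._pm_surv(rng)
        pm.iloc[0] = 1
        with caplog.at_level("WARNING"):
            kept = select_prognostic_pairs(pm, time, event, alpha=1.0)
        assert pm.index[0] not in kept
        assert set(kept) == set(pm.index[1:])  # alpha=1 keeps every testable pair


class TestLassoCox:
    def _data(self, rng, n=40, p=3, beta=(1.0, -0.8, 0.0)):
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)],
            index=[f"s{i}" for i in range(n)],
        )
        eta = X.to_numpy() @ np.array(beta[:p])
        time = pd.Series(rng.exponential(1.0 / (0.05 * np.exp(eta))), index=X.index)
        event = pd.Series((rng.uniform(size=n) > 0.25).astype(int), index=X.index)
        return X, time, event

    def test_huge_penalty_zeroes_everything(self, rng):
        X, time, event = self._data(rng)
        coef, meta = fit_lasso_cox(X, time, event, penalty=1e6)
        assert (coef == 0).all()

    def test_zero_penalty_matches_newton_oracle(self, rng):
        X, time, event = self._data(rng)
        coef, _ = fit_lasso_cox(X, time, event, penalty=0)
        oracle = cox_newton(X.to_numpy(), time.to_numpy(), event.to_numpy())
        assert np.allclose(coef.to_numpy(), oracle, atol=1e-6)

    def test_cross_validated_fit_is_deterministic(self, rng):
        X, time, event = self._data(rng, n=120)
        a, meta_a = fit_lasso_cox(X, time, event, folds=5, seed=3)
        b, meta_b = fit_lasso_cox(X, time, event, folds=5, seed=3)
        assert a.equals(b) and meta_a == meta_b

    def test_no_events_rejected(self, rng):
        X, time, event = self._data(rng)
        with pytest.raises(DomainError):
            fit_lasso_cox(X, time, event * 0, penalty=1.0)


class TestFinalCox:
    def test_univariate_matches_bisection_oracle(self, rng):
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        time = pd.Series(rng.exponential(1.0 / (0.05 * np.exp(0.9 * x))), index=range(n))
        event = pd.Series(np.ones(n, dtype=int), index=range(n))
        X = pd.DataFrame({"pair": x}, index=range(n))
        coef = fit_final_cox(X, time, event, retention="keep_all")
        oracle = univariate_cox_bisection(x, time.to_numpy(), event.to_numpy())
        assert coef["pair"] == pytest.approx(oracle, abs=1e-6)

    def test_null_feature_dropped_by_wald_rule(self, caplog):
        local = np.random.default_rng(0)
        n = 400
        X = pd.DataFrame({"noise": local.normal(size=n)}, index=range(n))
        time = pd.Series(local.exponential(30, n), index=range(n))
        event = pd.Series((local.uniform(size=n) > 0.3).astype(int), index=range(n))
        with caplog.at_level("WARNING"):
            coef = fit_final_cox(X, time, event)
        assert coef.empty

    def test_planted_sign_recovered(self, rng):
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        time = pd.Series(rng.exponential(1.0 / (0.02 * np.exp(1.2 * x))), index=range(n))
        event = pd.Series(np.ones(n, dtype=int), index=range(n))
        coef = fit_final_cox(pd.DataFrame({"p": x}, index=range(n)), time, event)
        assert coef["p"] > 0


class TestComputeTcrpi:
    def test_formula_arithmetic(self):
        pm = pd.DataFrame(
            [[1, 0], [1, 1]], index=["A|B", "C|D"], columns=["s1", "s2"]
        )
        scores = compute_tcrpi(pm, {"A|B": 0.5, "C|D": -0.25})
        assert scores["s1"] == pytest.approx(0.25)
        assert scores["s2"] == pytest.approx(-0.25)
        assert (compute_tcrpi(pm, {"A|B": 0.0, "C|D": 0.0}) == 0).all()

    def test_missing_pair_is_schema_error(self):
        pm = pd.DataFrame([[1]], index=["A|B"], columns=["s1"])
        with pytest.raises(SchemaError):
            compute_tcrpi(pm, {"A|B": 1.0, "X|Y": 2.0})


class TestTimeDependentRoc:
    def test_perfect_marker_auc_one(self):
        time = np.array([10.0, 20.0, 30.0, 80.0, 90.0, 100.0])
        event = np.ones(6, dtype=int)
        scores = pd.Series([6.0, 5.0, 4.0, 1.0, 2.0, 3.0])
        roc = time_dependent_roc(scores, time, event, t_star=60.0)
        assert roc.auc == pytest.approx(1.0)
        cutoff = select_cutoff(roc)
        d = roc.points.set_index("threshold")
        assert d.loc[cutoff, "sensitivity"] == 1.0 and d.loc[cutoff, "specificity"] == 1.0

    def test_uncensored_reduces_to_binary_roc(self, rng):
        n = 50
        time = rng.exponential(50, n)
        event = np.ones(n, dtype=int)
        scores = pd.Series(rng.normal(size=n))
        t_star = float(np.median(time))
        labels = (time <= t_star).astype(int)
        roc = time_dependent_roc(scores, time, event, t_star)
        assert roc.auc == pytest.approx(auc_u_statistic(scores.to_numpy(), labels), abs=1e-9)
        for _, row in roc.points.iterrows():
            hi = scores.to_numpy() > row["threshold"]
            assert row["sensitivity"] == pytest.approx(
                (hi & (labels == 1)).sum() / labels.sum(), abs=1e-9
            )
            assert row["specificity"] == pytest.approx(
                (~hi & (labels == 0)).sum() / (labels == 0).sum(), abs=1e-9
            )

    def test_permuted_scores_auc_half_on_average(self, rng):
        n = 60
        time = rng.exponential(40, n)
        event = (rng.uniform(size=n) > 0.3).astype(int)
        scores = rng.normal(size=n)
        aucs = []
        for _ in range(500):
            perm = rng.permutation(scores)
            aucs.append(time_dependent_roc(pd.Series(perm), time, event, 30.0).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_preconditions(self):
        time = np.array([100.0, 120.0, 130.0, 150.0])
        event = np.array([1, 1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DomainError):
            time_dependent_roc(scores, time, event, t_star=60.0)  # no early events
        with pytest.raises(DomainError):
            time_dependent_roc(scores, time, event, t_star=200.0)  # nobody at risk later


class TestSelectCutoff:
    def test_matches_bruteforce_on_random_curves(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 12))
            pts = pd.DataFrame(
                {
                    "threshold": np.sort(rng.normal(size=k)),
                    "sensitivity": rng.uniform(size=k),
                    "specificity": rng.uniform(size=k),
                }
            )
            roc = ROCCurve(points=pts, auc=0.5)
            got = select_cutoff(roc)
            d = np.sqrt((1 - pts["sensitivity"]) ** 2 + (1 - pts["specificity"]) ** 2)
            best = d.min()
            candidates = pts.loc[np.abs(d - best) < 1e-15, "threshold"]
            assert got == pytest.approx(candidates.min())

    def test_tie_broken_to_smaller_threshold(self):
        pts = pd.DataFrame(
            {
                "threshold": [1.0, 2.0, 3.0],
                "sensitivity": [0.8, 0.5, 0.8],
                "specificity": [0.6, 0.5, 0.6],
            }
        )
        assert select_cutoff(ROCCurve(points=pts, auc=0.5)) == 1.0

    def test_empty_curve_rejected(self):
        with pytest.raises(DomainError):
            select_cutoff(ROCCurve(points=pd.DataFrame(columns=["threshold"]), auc=0.5))


class TestAssignRisk:
    def test_threshold_and_tie_convention(self):
        scores = pd.Series([0.2, 0.5, 0.9], index=["a", "b", "c"])
        risk = assign_risk(scores, cutoff=0.5)
        assert list(risk.group) == ["low", "low", "high"]  # tie falls to low
        all_low = assign_risk(scores, cutoff=2.0)
        assert (all_low.group == "low").all()
        with pytest.raises(DomainError):
            assign_risk(scores, cutoff=np.inf)


class TestCompositeIndex:
    def test_published_style_arithmetic(self):
        model = CompositeIndexModel(
            terms=[("age", 0.627), ("stage", 0.538), ("tcrpi", 0.334)],
            encodings={},
        )
        feats = pd.DataFrame({"age": [1.0], "stage": [1.0], "tcrpi": [1.0]})
        assert model.score(feats).iloc[0] == pytest.approx(1.499)

    def test_encoding_defaults(self):
        clinical = pd.DataFrame(
            {
                "age_years": [70.0, 50.0],
                "gender": ["male", "female"],
                "stage": ["IV", "I"],
                "grade": ["high", "low"],
            },
            index=["a", "b"],
        )
        tcrpi = pd.Series([1.5, -0.5], index=["a", "b"])
        feats = encode_clinical(clinical, tcrpi)
        assert feats.loc["a"].tolist() == [1.0, 1.0, 1.0, 1.0, 1.5]
        assert feats.loc["b"].tolist() == [0.0, 0.0, 0.0, 0.0, -0.5]

    def test_incomplete_cases_dropped(self):
        clinical = pd.DataFrame(
            {
                "age_years": [70.0, np.nan],
                "gender": ["male", "male"],
                "stage": ["IV", "II"],
                "grade": ["high", "low"],
            },
            index=["a", "b"],
        )
        feats = encode_clinical(clinical, pd.Series([1.0, 2.0], index=["a", "b"]))
        assert list(feats.index) == ["a"]

    def test_pure_index_signal_keeps_index_only(self, rng):
        n = 500
        idx = [f"s{i}" for i in range(n)]
        tcrpi = pd.Series(rng.normal(size=n), index=idx)
        clinical = pd.DataFrame(
            {
                "age_years": rng.normal(65, 10, n),
                "gender": rng.choice(["male", "female"], n),
                "stage": rng.choice(["I", "II", "III", "IV"], n),
                "grade": rng.choice(["low", "high"], n),
            },
            index=idx,
        )
        time = pd.Series(rng.exponential(1.0 / (0.02 * np.exp(tcrpi)), n), index=idx)
        event = pd.Series(np.ones(n, dtype=int), index=idx)
        model = fit_ctcpi(tcrpi, clinical, time, event)
        assert [n for n, _ in model.terms] == ["tcrpi"]
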