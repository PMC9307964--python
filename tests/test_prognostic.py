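from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from oracles import auc_no_censoring_oracle, wilcoxon_exact_oracle

from exopair.data_io import PairMatrix, RiskModel, SurvivalTable
from exopair.pairing import encode_pairs
from exopair.prognostic_model import (
    _univariate_cox,
    clinical_association,
    cox_partial_loglik,
    decision_curve,
    dichotomize_and_test,
    independence_cox,
    lasso_cox_select,
    risk_score,
    stepwise_aic_cox,
    time_dependent_roc,
    univariate_cox_screen,
)
from exopair.stats import rank_sum_test
from exopair.synthetic_data import SimulationConfig, simulate_expression, simulate_survival


def _surv(times, events, samples=None, covs=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events}, index=pd.Index(samples))
    if covs:
        for k, v in covs.items():
            df[k] = v
    return SurvivalTable(df)


def _pm(binary, samples=None):
    binary = np.asarray(binary, dtype=np.int8)
    samples = samples or [f"s{j}" for j in range(binary.shape[1])]
    return PairMatrix(
        pd.DataFrame(binary, index=[f"a{i}|b{i}" for i in range(binary.shape[0])],
                     columns=samples)
    )


class TestUnivariateCox:
    def test_matches_lifelines_on_continuous_data(self):
        rng = np.random.default_rng(0)
        n = 120
        x = rng.normal(size=n)
        t_event = rng.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
        c = rng.exponential(40, n)
        e = (t_event <= c).astype(int)
        t = np.minimum(t_event, c)
        beta, se, ok = _univariate_cox(x, t, e)
        df = pd.DataFrame({"x": x, "time": t, "event": e})
        cph = CoxPHFitter().fit(df, "time", "event")
        assert ok
        assert beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_null_pair_gives_hr_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        s = rng.integers(0, 2, n)
        t = rng.exponential(50, n)
        screen = univariate_cox_screen(_pm(s[None, :]), _surv(t, np.ones(n, dtype=int)))
        assert screen["hr"].iloc[0] == pytest.approx(1.0, abs=0.15)
        assert not screen["selected"].iloc[0]

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            univariate_cox_screen(_pm([[0, 1, 0]]), _surv([1, 2, 3], [0, 0, 0]))

    def test_separated_pair_dropped(self):
        # events only when S = 1 and far earlier: drives beta to +inf
        s = np.array([[1, 1, 1, 1, 0, 0, 0, 0]])
        t = [0.1, 0.2, 0.3, 0.4, 50, 60, 70, 80]
        e = [1, 1, 1, 1, 0, 0, 0, 0]
        out = univariate_cox_screen(_pm(s), _surv(t, e))
        assert len(out) == 0


class TestPartialLoglik:
    def test_matches_lifelines_loglik(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=(n, 2))
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        df = pd.DataFrame({"x0": x[:, 0], "x1": x[:, 1], "time": t, "event": e})
        cph = CoxPHFitter().fit(df, "time", "event")
        beta = cph.params_.to_numpy()
        ll = cox_partial_loglik(x @ beta, t, e)
        assert ll == pytest.approx(float(cph.log_likelihood_), rel=1e-6)


class TestLassoSelect:
    @staticmethod
    def _planted_data(seed, n=300, n_noise=20):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 2, size=(n_noise + 1, n))
        eta = 1.2 * s[0]
        t = rng.exponential(1.0 / (0.02 * np.exp(eta)))
        e = np.ones(n, dtype=int)
        return _pm(s), _surv(t, e)

    def test_strong_pair_always_selected(self):
        pm, surv = self._planted_data(3)
        sel = lasso_cox_select(pm, surv, n_cycles=10, seed=0)
        assert sel.frequencies["a0|b0"] == pytest.approx(1.0)
        assert "a0|b0" in sel.selected

    def test_all_null_yields_no_confident_selection(self):
        rng = np.random.default_rng(4)
        n = 200
        s = rng.integers(0, 2, size=(10, n))
        t = rng.exponential(30, n)
        pm, surv = _pm(s), _surv(t, np.ones(n, dtype=int))
        try:
            sel = lasso_cox_select(pm, surv, n_cycles=10, seed=0)
        except ValueError:
            return  # nothing ever selected: acceptable outcome under the null
        assert float(sel.frequencies.median()) <= 0.5

    def test_too_few_candidates_rejected(self):
        pm, surv = self._planted_data(5)
        with pytest.raises(ValueError, match=">= 2"):
            lasso_cox_select(pm.subset_pairs(["a0|b0"]), surv, n_cycles=2)

    def test_folds_bounded_by_events(self):
        pm, surv = self._planted_data(6, n=30)
        surv.data["event"] = [1] * 5 + [0] * 25
        with pytest.raises(ValueError, match="folds"):
            lasso_cox_select(pm, surv, n_cycles=2, folds=10)


class TestStepwiseAic:
    def test_noise_covariate_eliminated(self):
        pm, surv = TestLassoSelect._planted_data(7, n=500, n_noise=1)
        model = stepwise_aic_cox(pm, surv)
        assert "a0|b0" in model.pairs
        assert model.training_meta["aic"] <= model.training_meta["aic_full"] + 1e-9

    def test_single_strong_covariate_retained(self):
        pm, surv = TestLassoSelect._planted_data(8, n=400, n_noise=0)
        model = stepwise_aic_cox(pm, surv)
        assert model.pairs == ["a0|b0"]
        assert model.beta[0] == pytest.approx(1.2, abs=0.4)


class TestRiskScore:
    def test_dot_product_definition(self):
        pm = _pm([[1, 0], [0, 1]])
        model = RiskModel(pairs=["a0|b0", "a1|b1"], beta=[1.0, -1.0])
        assert risk_score(model, pm).tolist() == [1.0, -1.0]

    def test_all_zero_indicators(self):
        pm = _pm([[0, 0], [0, 0]])
        model = RiskModel(pairs=["a0|b0", "a1|b1"], beta=[2.0, 3.0])
        assert risk_score(model, pm).tolist() == [0.0, 0.0]

    def test_random_equals_hand_dot(self):
        rng = np.random.default_rng(9)
        s = rng.integers(0, 2, size=(8, 5))
        beta = rng.normal(size=8)
        pm = _pm(s)
        model = RiskModel(pairs=pm.pair_ids, beta=beta.tolist())
        assert np.allclose(risk_score(model, pm).to_numpy(), beta @ s)

    def test_missing_pair_rejected(self):
        pm = _pm([[1, 0]])
        with pytest.raises(KeyError):
            risk_score(RiskModel(pairs=["x|y"], beta=[1.0]), pm)


class TestTimeDependentRoc:
    def test_perfect_separation(self):
        t = np.array([1, 2, 3, 20, 30, 40], dtype=float)
        e = np.array([1, 1, 1, 0, 0, 0])
        sc = pd.Series([10, 9, 8, 1, 2, 3], index=[f"s{i}" for i in range(6)], dtype=float)
        roc = time_dependent_roc(sc, _surv(t, e), horizon=10)
        assert roc.auc == pytest.approx(1.0)
        assert 3 <= roc.cutoff < 8
        assert roc.youden == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_no_censoring_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        t = rng.exponential(10, n)
        sc = pd.Series(rng.integers(0, 5, n).astype(float), index=[f"s{i}" for i in range(n)])
        horizon = float(np.median(t))
        roc = time_dependent_roc(sc, _surv(t, np.ones(n, dtype=int)), horizon)
        assert roc.auc == pytest.approx(
            auc_no_censoring_oracle(sc.to_numpy(), t, np.ones(n, dtype=int), horizon)
        )

    def test_cutoff_attains_max_youden(self):
        rng = np.random.default_rng(5)
        n = 80
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        sc = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        roc = time_dependent_roc(sc, _surv(t, e), float(np.median(t)))
        j = roc.sensitivity + roc.specificity - 1.0
        assert roc.youden == pytest.approx(j.max())
        assert roc.cutoff == roc.thresholds[np.argmax(j)]

    def test_no_events_before_horizon_rejected(self):
        sc = pd.Series([1.0, 2.0], index=["s0", "s1"])
        with pytest.raises(ValueError, match="events"):
            time_dependent_roc(sc, _surv([10, 20], [1, 1]), horizon=5)


class TestDichotomize:
    def test_degenerate_cutoff_rejected(self):
        sc = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="one group"):
            dichotomize_and_test(sc, 10.0, _surv([1, 2, 3], [1, 1, 1]))

    def test_planted_model_detected(self, small_study):
        truth = small_study.truth
        planted = [p for p, _ in truth.planted_pairs]
        pm = encode_pairs(small_study.tumor1, sorted({g for p in planted for g in p.split("|")}))
        model = RiskModel(pairs=planted, beta=[b for _, b in truth.planted_pairs])
        sc = risk_score(model, pm)
        _labels, _curves, _stat, p = dichotomize_and_test(sc, float(sc.median()),
                                                          small_study.survival1)
        assert p < 0.001


class TestClinicalAssociation:
    def test_exact_wilcoxon_worked_example(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rank_sum_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        u, p = rank_sum_test(x, y)
        u_o, p_o = wilcoxon_exact_oracle(x, y)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o)

    def test_balanced_table_null(self):
        samples = [f"s{i}" for i in range(20)]
        labels = pd.Series(["high"] * 10 + ["low"] * 10, index=samples)
        scores = pd.Series(np.arange(20, dtype=float), index=samples)
        cov = pd.DataFrame({"sex": (["m"] * 5 + ["f"] * 5) * 2}, index=samples)
        out = clinical_association(scores, labels, cov)
        chi = out[out["test"] == "chi_square"].iloc[0]
        assert chi["statistic"] == pytest.approx(0.0)

    def test_single_level_covariate_skipped(self):
        samples = [f"s{i}" for i in range(6)]
        labels = pd.Series(["high", "low"] * 3, index=samples)
        scores = pd.Series(np.arange(6, dtype=float), index=samples)
        cov = pd.DataFrame({"site": ["x"] * 6}, index=samples)
        assert clinical_association(scores, labels, cov).empty


class TestIndependenceCox:
    def test_score_independent_of_noise_stage(self, small_study):
        truth = small_study.truth
        planted = [p for p, _ in truth.planted_pairs]
        pm = encode_pairs(small_study.tumor1, sorted({g for p in planted for g in p.split("|")}))
        model = RiskModel(pairs=planted, beta=[b for _, b in truth.planted_pairs])
        sc = risk_score(model, pm)
        out = independence_cox(sc, small_study.survival1.covariates, small_study.survival1)
        assert out["multivariate"].loc["risk_score", "pvalue"] < 0.05
        assert out["univariate"].loc["risk_score", "hr"] > 1.0

    def test_duplicated_covariate_collinearity_path(self):
        rng = np.random.default_rng(10)
        n = 60
        t = rng.exponential(10, n)
        samples = [f"s{i}" for i in range(n)]
        sc = pd.Series(rng.normal(size=n), index=samples)
        cov = pd.DataFrame({"a": rng.normal(size=n)}, index=samples)
        cov["b"] = cov["a"]
        out = independence_cox(sc, cov, _surv(t, np.ones(n, dtype=int), samples=samples))
        assert {"a", "b"} <= set(out["multivariate"].index)


class TestDecisionCurve:
    @staticmethod
    def _data(seed=11, n=200):
        rng = np.random.default_rng(seed)
        sc = rng.normal(size=n)
        rate = 0.05 * np.exp(sc)
        t = rng.exponential(1.0 / rate)
        samples = [f"s{i}" for i in range(n)]
        return pd.Series(sc, index=samples), _surv(t, np.ones(n, dtype=int), samples=samples)

    def test_reference_curves(self):
        sc, surv = self._data()
        out = decision_curve(sc, surv, horizon=10.0, thresholds=[0.1, 0.3, 0.5])
        assert np.allclose(out["nb_none"], 0.0)
        time = surv.time.to_numpy()
        prev = float(np.mean(time <= 10.0))
        for _, row in out.iterrows():
            pt = row["threshold"]
            assert row["nb_all"] == pytest.approx(prev - (1 - prev) * pt / (1 - pt))

    def test_perfect_marker_reaches_prevalence(self):
        samples = [f"s{i}" for i in range(40)]
        sc = pd.Series([5.0] * 10 + [-5.0] * 30, index=samples)
        t = [1.0] * 10 + [100.0] * 30
        surv = _surv(t, np.ones(40, dtype=int), samples=samples)
        out = decision_curve(sc, surv, horizon=10.0, thresholds=[0.1, 0.25, 0.5, 0.75])
        assert np.allclose(out["nb_model"], 0.25, atol=1e-6)

    def test_empty_grid_rejected(self):
        sc, surv = self._data()
        with pytest.raises(ValueError, match="threshold"):
            decision_curve(sc, surv, horizon=10.0, thresholds=[])
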