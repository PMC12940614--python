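"""Effect estimation: responder rule, Cox, logistic, AUC, KM, group tests."""

import math

import numpy as np
import pandas as pd
import pytest

from tlsmeta.association import (
    auc,
    classify_response,
    compare_auc,
    compare_groups,
    correlate_signatures,
    cox_partial_loglik,
    fit_cox_univariate,
    fit_logistic_univariate,
    km_logrank,
)


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "recist,pfs_time,pfs_event,expected",
        [
            ("CR", None, None, "R"),
            ("PR", None, None, "R"),
            ("PD", None, None, "NR"),
            ("SD", 5.0, 1, "NR"),  # progression within the 6-month window
            ("SD", 7.0, 1, "R"),  # progression after the window
            ("SD", 3.0, 0, "R"),  # censored without event
            ("SD", None, None, "non_assessable"),
            (None, 4.0, 1, "NR"),  # RECIST missing: 6-month PFS rule
            (None, 10.0, 0, "R"),
        ],
    )
    def test_rule(self, recist, pfs_time, pfs_event, expected):
        assert classify_response(recist, pfs_time, pfs_event) == expected

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            classify_response(None, None, None)


# 10-subject fixture with tied event times to exercise Breslow handling
COX_FIXTURE = dict(
    score=[0.5, -1.2, 0.3, 2.1, -0.7, 1.4, 0.0, -2.0, 0.9, -0.4],
    time=[5.0, 8.0, 5.0, 2.0, 12.0, 3.0, 8.0, 15.0, 2.0, 9.0],
    event=[1, 1, 1, 1, 0, 1, 1, 0, 1, 1],
)


class TestCox:
    def test_symmetric_design_gives_zero(self):
        # mirror-image groups: swapping the score labels leaves the data
        # invariant, so the estimate must vanish
        score = [1, 1, 1, -1, -1, -1]
        time = [2.0, 5.0, 9.0, 2.0, 5.0, 9.0]
        event = [1, 1, 0, 1, 1, 0]
        fit = fit_cox_univariate(score, time, event)
        assert abs(fit.estimate) < 1e-8

    def test_matches_grid_search_oracle(self):
        fit = fit_cox_univariate(**COX_FIXTURE)
        grid = np.linspace(fit.estimate - 0.3, fit.estimate + 0.3, 12001)
        ll = [cox_partial_loglik(b, **COX_FIXTURE) for b in grid]
        best = grid[int(np.argmax(ll))]
        assert fit.estimate == pytest.approx(best, abs=1e-4)
        assert fit.converged

    def test_matches_lifelines_on_untied_data(self):
        # without tied event times Breslow and Efron likelihoods coincide,
        # so lifelines serves as an independent cross-check
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(17)
        data = dict(
            score=rng.normal(size=40).tolist(),
            time=(rng.exponential(10, size=40) + 0.1).tolist(),
            event=(rng.random(40) < 0.7).astype(int).tolist(),
        )
        fit = fit_cox_univariate(**data)
        df = pd.DataFrame({"t": data["time"], "e": data["event"], "x": data["score"]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.estimate == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_scale_equivariance(self):
        fit1 = fit_cox_univariate(**COX_FIXTURE)
        scaled = dict(COX_FIXTURE, score=[10 * s for s in COX_FIXTURE["score"]])
        fit10 = fit_cox_univariate(**scaled)
        assert fit10.estimate == pytest.approx(fit1.estimate / 10, rel=1e-6)
        assert fit10.se == pytest.approx(fit1.se / 10, rel=1e-6)
        assert fit10.p == pytest.approx(fit1.p, rel=1e-6)

    def test_location_invariance(self):
        fit1 = fit_cox_univariate(**COX_FIXTURE)
        shifted = dict(COX_FIXTURE, score=[s + 100 for s in COX_FIXTURE["score"]])
        fit2 = fit_cox_univariate(**shifted)
        assert fit2.estimate == pytest.approx(fit1.estimate, abs=1e-8)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox_univariate([1, 2, 3], [1.0, 2.0, 3.0], [1, 0, 0])
        with pytest.raises(ValueError, match="variance"):
            fit_cox_univariate([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])


class TestLogistic:
    def test_binary_predictor_closed_form(self):
        # 2x2 table (a,b,c,d) = (6,2,3,9): logOR = log(ad/bc) = log(9)
        x = [1] * 8 + [0] * 12
        y = [1] * 6 + [0] * 2 + [1] * 3 + [0] * 9
        fit = fit_logistic_univariate(x, y)
        assert fit.estimate == pytest.approx(math.log(9.0), abs=1e-6)
        assert fit.converged

    def test_label_flip_negates(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        f1 = fit_logistic_univariate(x, y)
        f2 = fit_logistic_univariate(x, 1 - y)
        assert f2.estimate == pytest.approx(-f1.estimate, abs=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
        fit = fit_logistic_univariate(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.estimate == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_separation_falls_back_to_firth(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_logistic_univariate(x, y)
        assert not fit.converged
        assert fit.method == "firth"
        assert math.isfinite(fit.estimate) and math.isfinite(fit.se)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_logistic_univariate([1.0, 2.0], ["R", "R"])


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([1, 2, 3, 4], ["NR", "NR", "R", "R"]) == 1.0

    def test_all_ties(self):
        assert auc([5, 5, 5, 5], ["NR", "R", "NR", "R"]) == 0.5

    def test_pair_counting(self):
        # pairs (NR, R): (1,2)+, (1,4)+, (3,2)-, (3,4)+ -> 3/4
        assert auc([1, 2, 3, 4], ["NR", "R", "NR", "R"]) == 0.75

    def test_complement_identity(self, rng):
        for _ in range(20):
            s = rng.normal(size=30)
            y = (rng.random(30) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            assert auc(s, y) + auc(-s, y) == pytest.approx(1.0, abs=1e-12)


class TestCompareAuc:
    def test_identical_scores(self, rng):
        s = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(int)
        res = compare_auc(s, s, y)
        assert res.delta == 0.0 and res.p == 1.0

    def test_complement_identity(self, rng):
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        res = compare_auc(s, -s, y)
        assert res.delta == pytest.approx(2 * res.auc_a - 1, abs=1e-12)

    def test_variance_matches_bootstrap(self):
        rng = np.random.default_rng(5)
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        a = rng.normal(size=10) + 0.8 * y
        b = rng.normal(size=10) + 0.5 * y
        res = compare_auc(a, b, y)
        delong_var = (res.delta / res.z) ** 2
        deltas = []
        while len(deltas) < 2000:
            idx = rng.integers(0, 10, size=10)
            if y[idx].min() == y[idx].max():
                continue
            deltas.append(auc(a[idx], y[idx]) - auc(b[idx], y[idx]))
        boot_var = float(np.var(deltas, ddof=1))
        assert delong_var == pytest.approx(boot_var, rel=0.30)


class TestKmLogrank:
    def test_identical_arms(self):
        scores = pd.Series([1, 1, 1, 10, 10, 10], dtype=float)
        time = [3.0, 6.0, 9.0, 3.0, 6.0, 9.0]
        event = [1, 1, 1, 1, 1, 1]
        res = km_logrank(scores, time, event)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_logrank(self):
        # 6 subjects, no censoring, no ties; observed - expected by hand
        scores = pd.Series([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [1, 1, 1, 1, 1, 1]
        res = km_logrank(scores, time, event)
        # high arm dies at t=1,2,3; expected events in the high arm:
        # 3/6 + 2/5 + 1/4 + 0 + 0 + 0 = 1.15; O-E = 3 - 1.15 = 1.85
        # hypergeometric variance n1*n0/n^2 per (single-event) time; zero
        # once the high arm is exhausted
        expected = 3 / 6 + 2 / 5 + 1 / 4
        o_minus_e = 3 - expected
        v = (3 * 3 / 36) + (2 * 3 / 25) + (1 * 3 / 16)
        assert res.chi2 == pytest.approx(o_minus_e**2 / v, rel=1e-6)

    def test_curves_non_increasing(self, rng):
        scores = pd.Series(rng.normal(size=30))
        time = rng.exponential(10, size=30) + 0.1
        event = (rng.random(30) < 0.7).astype(int)
        res = km_logrank(scores, time, event)
        for curve in res.curves.values():
            assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)
        assert res.method == "permutation_exact"

    def test_fisher_two_by_two(self):
        x = ["yes"] * 3 + ["no"]
        y = ["yes"] + ["no"] * 3
        res = compare_groups(x, y)
        assert res.method == "fisher"
        assert res.p == pytest.approx(0.4857142857, abs=1e-9)

    def test_small_samples_use_permutation(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], seed=0)
        assert res.method == "permutation_exact"
        # most extreme assignment: p is at the 2/C(8,4) granularity floor
        assert res.p == pytest.approx(2 / 70, abs=1e-12)

    def test_large_samples_use_wilcoxon(self, rng):
        res = compare_groups(rng.normal(size=15), rng.normal(size=15))
        assert res.method == "wilcoxon"

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestCorrelateSignatures:
    def _frames(self, rng):
        out = {}
        for c in range(3):
            base = rng.normal(size=25)
            out[f"c{c}"] = pd.DataFrame(
                {
                    "sigA": base,
                    "sigB": np.exp(base),  # strictly monotone transform
                    "sigC": rng.normal(size=25),
                }
            )
        return out

    def test_self_and_monotone_transform(self, rng):
        med = correlate_signatures(self._frames(rng))
        assert med.loc["sigA", "sigA"] == 1.0
        assert med.loc["sigA", "sigB"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        frames = {
            "c1": pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]}),
        }
        med = correlate_signatures(frames)
        assert med.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_vector_warns_missing(self):
        frames = {
            "c1": pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}),
        }
        with pytest.warns(UserWarning, match="constant"):
            med = correlate_signatures(frames)
        assert np.isnan(med.loc["a", "b"])
        assert med.loc["b", "b"] == 1.0
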