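import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

import epiprog as ep


def _sig(up=("u1", "u2"), down=("d1",)):
    return ep.Signature("toy",
                        frozenset((g, "") for g in up),
                        frozenset((g, "") for g in down))


class TestZscore:
    def test_basic_arithmetic(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=["p1", "p2", "p3"])
        z = ep.zscore(m)
        assert np.allclose(z.loc["f"], [-1.0, 0.0, 1.0])

    def test_mean_zero_variance_one(self):
        rng = np.random.default_rng(81)
        m = pd.DataFrame(rng.normal(3, 7, (30, 40)))
        z = ep.zscore(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.var(axis=1, ddof=1) - 1).max() < 1e-10

    def test_constant_feature_dropped_not_nan(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["c", "v"])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = ep.zscore(m)
        assert list(z.index) == ["v"]
        assert not z.isna().any().any()

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            ep.zscore(pd.DataFrame([[1.0]]))


class TestSignatureScore:
    def _z(self, values):
        return pd.DataFrame(values, columns=["p1"])

    def test_worked_combined_example(self):
        # up z = (1.0, 0.5), down z = (-0.5):
        # combined = (1.0 + 0.5 - (-0.5)) / 3 = 2/3
        z = pd.DataFrame({"p1": [1.0, 0.5, -0.5]}, index=["u1", "u2", "d1"])
        s = ep.signature_score(z, _sig())
        assert s.loc["p1", "combined_score"] == pytest.approx(2 / 3)
        assert s.loc["p1", "up_score"] == pytest.approx(0.75)
        assert s.loc["p1", "down_score"] == pytest.approx(-0.5)

    def test_empty_down_set_collapses_to_up_mean(self):
        z = pd.DataFrame({"p1": [1.0, 0.5]}, index=["u1", "u2"])
        s = ep.signature_score(z, _sig(down=()))
        assert s.loc["p1", "combined_score"] == s.loc["p1", "up_score"]

    def test_down_weighting_identity(self):
        # moving a down gene to the up set with negated z leaves the
        # combined score unchanged
        rng = np.random.default_rng(82)
        z = pd.DataFrame(rng.normal(size=(3, 10)), index=["u1", "u2", "d1"])
        s1 = ep.signature_score(z, _sig())["combined_score"]
        z2 = z.copy()
        z2.loc["d1"] = -z2.loc["d1"]
        s2 = ep.signature_score(z2, _sig(up=("u1", "u2", "d1"), down=()))["combined_score"]
        assert np.allclose(s1, s2)

    def test_linearity_in_z(self):
        rng = np.random.default_rng(83)
        z = pd.DataFrame(rng.normal(size=(3, 8)), index=["u1", "u2", "d1"])
        s1 = ep.signature_score(z, _sig())["combined_score"]
        s3 = ep.signature_score(3.0 * z, _sig())["combined_score"]
        assert np.allclose(3.0 * s1, s3)

    def test_no_overlap_rejected(self):
        z = pd.DataFrame({"p1": [1.0]}, index=["other"])
        with pytest.raises(ValueError, match="toy"):
            ep.signature_score(z, _sig())


class TestDichotomizeAndQuartiles:
    def test_even_split_without_ties(self):
        s = pd.Series(np.arange(1, 101, dtype=float))
        g = ep.dichotomize_median(s)
        assert (g == "high").sum() == 50
        assert (g == "low").sum() == 50

    def test_median_ties_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0])
        g = ep.dichotomize_median(s)
        assert list(g) == ["low", "low", "low", "high"]

    def test_negation_swaps_groups(self):
        s = pd.Series([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        g1, g2 = ep.dichotomize_median(s), ep.dichotomize_median(-s)
        assert ((g1 == "high") == (g2 == "low")).all()

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ep.dichotomize_median(pd.Series([1.0, 1.0, 1.0]))

    def test_quartile_boundaries_strict(self):
        v = pd.Series(np.arange(1, 101, dtype=float))
        g = ep.quartile_stratify(v)
        # 25th percentile (linear interpolation) = 25.75; strictly below
        assert (g == "low").sum() == 25
        assert (g == "high").sum() == 25
        assert (g == "excluded").sum() == 50
        assert set(v[g == "low"]) == set(np.arange(1.0, 26.0))
        assert set(v[g == "high"]) == set(np.arange(76.0, 101.0))

    def test_quartile_rank_invariance(self):
        rng = np.random.default_rng(84)
        v = pd.Series(rng.normal(size=60))
        g1 = ep.quartile_stratify(v)
        g2 = ep.quartile_stratify(np.exp(v) + 5)
        assert (g1 == g2).all()

    def test_quartile_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ep.quartile_stratify(pd.Series(np.ones(20)))


def logrank_oracle(time, event, g1_mask):
    """Independent risk-set enumeration of the two-group log-rank chi2."""
    records = sorted(zip(time, event, g1_mask))
    o_minus_e, var = 0.0, 0.0
    event_times = sorted({t for t, e, _ in records if e})
    for t in event_times:
        risk = [(tt, ee, gg) for tt, ee, gg in records if tt >= t]
        n = len(risk)
        n1 = sum(1 for _, _, gg in risk if gg)
        d = sum(1 for tt, ee, _ in risk if tt == t and ee)
        d1 = sum(1 for tt, ee, gg in risk if tt == t and ee and gg)
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e ** 2) / var if var > 0 else 0.0


class TestKmLogrank:
    def test_identical_groups_are_null(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 1, 1, 1, 1]
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        res, _ = ep.km_logrank(groups, time, event)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_logrank == pytest.approx(1.0)

    def test_interleaved_cohort_matches_hand_enumeration(self):
        time = [1, 3, 5, 2, 4, 6]
        event = [1, 1, 1, 1, 1, 1]
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        res, _ = ep.km_logrank(groups, time, event)
        expected = logrank_oracle(time, event, [True, True, True, False, False, False])
        assert res.logrank_chi2 == pytest.approx(expected, abs=1e-12)

    def test_matches_risk_set_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(85)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            time = rng.integers(1, 8, n).astype(float)  # force ties
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            g = rng.integers(0, 2, n).astype(bool)
            if g.all() or not g.any():
                g[0] = ~g[0]
            groups = pd.Series(np.where(g, "a", "b"))
            res, _ = ep.km_logrank(groups, time, event)
            assert res.logrank_chi2 == pytest.approx(
                logrank_oracle(time, event, g), abs=1e-9)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(86)
        time = rng.exponential(5, 80)
        event = rng.integers(0, 2, 80)
        event[0] = 1
        g = rng.integers(0, 2, 80).astype(bool)
        res, _ = ep.km_logrank(pd.Series(np.where(g, "a", "b")), time, event)
        ll = logrank_test(time[g], time[~g], event[g], event[~g])
        assert res.logrank_chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_logrank == pytest.approx(ll.p_value, rel=1e-9)

    def test_km_curve_reaches_zero_without_censoring(self):
        curve = ep.km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve["survival"].iloc[-1] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            ep.km_logrank(pd.Series(["a", "a"]), [1, 2], [1, 1])


class TestCoxFit:
    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(87)
        n = 150
        x = rng.standard_normal(n)
        lam = 0.2 * np.exp(0.5 * x)
        t = np.ceil(rng.exponential(1 / lam) * 4) / 4  # heavy ties
        c = rng.exponential(20, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        fit = ep.cox_fit(x, time, event)
        df = pd.DataFrame({"T": time, "E": event, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron ties too
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_adjusted_fit_matches_lifelines(self):
        rng = np.random.default_rng(88)
        n = 200
        x = rng.standard_normal(n)
        w = 0.5 * x + rng.standard_normal(n)
        lam = 0.2 * np.exp(0.4 * x + 0.3 * w)
        t = rng.exponential(1 / lam)
        event = np.ones(n, dtype=int)
        fit = ep.cox_fit(x, t, event, extra_covariates=w)
        df = pd.DataFrame({"T": t, "E": event, "x": x, "w": w})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.extra_betas[0] == pytest.approx(cph.params_["w"], abs=1e-6)

    def test_null_covariate_recovery(self):
        rng = np.random.default_rng(89)
        n = 1000
        x = rng.standard_normal(n)
        t = rng.exponential(5, n)
        fit = ep.cox_fit(x, t, np.ones(n, dtype=int))
        assert abs(fit.beta) < 0.1

    def test_duplicate_covariate_rejected(self):
        rng = np.random.default_rng(90)
        x = rng.standard_normal(50)
        t = rng.exponential(5, 50)
        with pytest.raises(Exception, match="[Ss]ingular|diverg"):
            ep.cox_fit(x, t, np.ones(50, dtype=int), extra_covariates=x.copy())

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ep.cox_fit(np.ones(30), np.arange(1, 31), np.ones(30, dtype=int))

    def test_ci_brackets_hazard_ratio(self):
        rng = np.random.default_rng(91)
        x = rng.standard_normal(300)
        t = rng.exponential(1 / (0.2 * np.exp(0.4 * x)))
        fit = ep.cox_fit(x, t, np.ones(300, dtype=int))
        assert fit.ci_low < fit.hazard_ratio < fit.ci_high
        assert 0 < fit.p_wald < 1


class TestCovariateAssociation:
    def test_identity_and_antisymmetry(self):
        v = np.arange(20, dtype=float)
        rho, _ = ep.covariate_association(v, v)
        assert rho == pytest.approx(1.0)
        rho, _ = ep.covariate_association(v, -v)
        assert rho == pytest.approx(-1.0)

    def test_null_pairs_uncorrelated(self):
        rng = np.random.default_rng(92)
        a = rng.normal(size=1000)
        b = rng.permutation(a)
        rho, p = ep.covariate_association(a, b)
        assert abs(rho) < 0.08

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ep.covariate_association(np.ones(10), np.arange(10))
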