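import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from itaemt import (
    ClinicalTable,
    ExpressionMatrix,
    FOUR_GROUP_LEVELS,
    ScoreVector,
    ValidationError,
    cox_score_test,
    fit_cox,
    four_group,
    hr_iqr,
    km_logrank,
    median_split,
    rank_emt_genes,
    simulate_survival_from_covariates,
    validate_genes,
)
from itaemt.survival import CoxResult, _bh_adjust


def _clin(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame(
        {"os_time": times, "os_event": events}, index=pd.Index(samples)))


def _X(clin, **cols):
    return pd.DataFrame(cols, index=clin.sample_ids)


def brute_loglik(x, time, event, beta):
    """Breslow log partial likelihood by explicit loops (scalar covariate)."""
    ll = 0.0
    for i in range(len(x)):
        if event[i] == 1:
            risk = [j for j in range(len(x)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def brute_km(times, events):
    """Product-limit estimator by explicit loops: {t: S(t)} at event times."""
    s = 1.0
    out = {}
    for t in sorted(set(times)):
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        if d > 0:
            s *= 1.0 - d / at_risk
        out[t] = s
    return out


class TestFitCox:
    def test_six_subject_scalar_oracle(self):
        # binary covariate with a tied event time
        x = np.array([1.0, 0, 1, 0, 1, 0])
        time = np.array([2.0, 4, 4, 6, 8, 10])
        event = np.array([1, 1, 1, 1, 0, 1])
        clin = _clin(time, event)
        res = fit_cox(_X(clin, g=x), clin)
        opt = optimize.minimize_scalar(
            lambda b: -brute_loglik(x, time, event, b),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        assert res.beta[0] == pytest.approx(opt.x, abs=1e-6)
        assert res.loglik == pytest.approx(-opt.fun, abs=1e-9)
        assert res.converged and res.n_events == 5

    def test_continuous_scalar_oracle(self):
        rng = np.random.default_rng(5)
        n = 40
        x = rng.normal(size=n)
        time = rng.exponential(scale=np.exp(-0.7 * x))
        event = rng.integers(0, 2, n) | 1  # guarantee events exist
        clin = _clin(time, event)
        res = fit_cox(_X(clin, g=x), clin)
        opt = optimize.minimize_scalar(
            lambda b: -brute_loglik(x, time, event, b),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-10})
        assert res.beta[0] == pytest.approx(opt.x, abs=1e-6)

    def test_matches_lifelines_two_covariates(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 120
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        time = rng.exponential(scale=np.exp(-(0.5 * x1 - 0.3 * x2)))
        event = (rng.uniform(size=n) < 0.8).astype(int)
        event[0] = 1
        clin = _clin(time, event)
        X = pd.DataFrame({"x1": x1, "x2": x2}, index=clin.sample_ids)
        res = fit_cox(X, clin)
        df = X.copy()
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        # continuous times: no ties, so Efron (lifelines) == Breslow
        assert res.beta == pytest.approx(cph.params_[["x1", "x2"]].to_numpy(), abs=1e-4)
        assert res.se == pytest.approx(
            cph.standard_errors_[["x1", "x2"]].to_numpy(), abs=1e-4)

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.normal(size=n)
        time = rng.exponential(scale=np.exp(-0.4 * x))
        event = np.ones(n, dtype=int)
        clin = _clin(time, event)
        r1 = fit_cox(pd.DataFrame({"g": x}, index=clin.sample_ids), clin)
        r2 = fit_cox(pd.DataFrame({"g": x + 1000.0}, index=clin.sample_ids), clin)
        assert r1.beta[0] == pytest.approx(r2.beta[0], abs=1e-8)
        assert r1.se[0] == pytest.approx(r2.se[0], abs=1e-8)

    def test_replication_scales_information(self):
        # doubling every subject leaves beta fixed and shrinks se by sqrt(2)
        x = np.array([1.0, 1, 0, 0, 1, 0, 1, 0])
        time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        c1 = _clin(time, event)
        r1 = fit_cox(_X(c1, g=x), c1)
        x2, t2, e2 = np.tile(x, 2), np.tile(time, 2), np.tile(event, 2)
        c2 = _clin(t2, e2)
        r2 = fit_cox(_X(c2, g=x2), c2)
        assert r2.beta[0] == pytest.approx(r1.beta[0], abs=1e-6)
        assert r2.se[0] == pytest.approx(r1.se[0] / np.sqrt(2), rel=1e-4)

    def test_zero_events_is_error(self):
        with pytest.raises(ValidationError, match="no events"):
            clin = _clin([1.0, 2.0, 3.0], [0, 0, 0])
            fit_cox(_X(clin, g=[1.0, 0.0, 1.0]), clin)

    def test_zero_variance_covariate_is_error(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            clin = _clin([1.0, 2.0, 3.0], [1, 0, 1])
            fit_cox(_X(clin, g=[2.0, 2.0, 2.0]), clin)

    def test_wald_p_from_z(self):
        x = np.array([1.0, 1, 0, 0, 1, 0])
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 1, 1, 1, 1, 1])
        clin = _clin(time, event)
        res = fit_cox(_X(clin, g=x), clin)
        z = res.beta[0] / res.se[0]
        assert res.wald_p[0] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-14)


class TestScoreTestLogRank:
    def test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(13)
        n = 100
        grp = rng.integers(0, 2, n)
        time = rng.exponential(scale=np.exp(-0.5 * grp))
        event = (rng.uniform(size=n) < 0.7).astype(int)
        event[:2] = 1
        clin = _clin(time, event)
        chi2, df, p = cox_score_test(
            pd.DataFrame({"g": grp.astype(float)}, index=clin.sample_ids), clin)
        labels = pd.Series(np.where(grp == 1, "high", "low"), index=clin.sample_ids)
        from itaemt.survival import GroupAssignment

        ga = GroupAssignment(labels=labels, cutpoints={}, levels=["low", "high"])
        _, lr_chi2, lr_df, lr_p = km_logrank(ga, clin)
        assert chi2 == pytest.approx(lr_chi2, abs=1e-8)
        assert df == lr_df == 1
        assert p == pytest.approx(lr_p, abs=1e-10)


class TestHrIqr:
    def _result(self, beta, se):
        return CoxResult(covariate_names=["S"], beta=np.array([beta]),
                         se=np.array([se]), wald_p=np.array([0.5]),
                         loglik=0.0, n=10, n_events=5, converged=True,
                         iterations=3)

    def _score(self, vals):
        return ScoreVector(pd.Series(vals, index=[f"s{i}" for i in range(len(vals))]),
                           name="S")

    def test_zero_beta_gives_unit_hr(self):
        out = hr_iqr(self._result(0.0, 0.2), self._score([0.0, 1, 2, 3, 4]))
        assert out["hr_iqr"] == pytest.approx(1.0)
        assert out["ci95_low"] < 1 < out["ci95_high"]

    def test_log2_beta_unit_iqr_gives_hr_two(self):
        # quartiles of 0..3 are 0.75 and 2.75: spread 2; use values with IQR 1
        score = self._score([0.0, 0.25, 0.5, 0.75, 1.0])
        assert np.subtract(*np.percentile(score.values, [75, 25])) == pytest.approx(0.5)
        out = hr_iqr(self._result(np.log(2.0) / 0.5, 0.1), score)
        assert out["hr_iqr"] == pytest.approx(2.0, abs=1e-12)

    def test_ci_formula_identity(self):
        score = self._score([1.0, 2, 3, 4, 5, 6, 7, 8])
        out = hr_iqr(self._result(0.3, 0.12), score)
        d = out["iqr"]
        assert out["ci95_low"] == pytest.approx(np.exp((0.3 - 1.959963985 * 0.12) * d))
        assert out["ci95_high"] == pytest.approx(np.exp((0.3 + 1.959963985 * 0.12) * d))

    def test_affine_rescale_invariance(self):
        """Rescaling the score by c divides beta by c and multiplies the
        IQR by c, leaving hr_iqr unchanged."""
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        time = rng.exponential(scale=np.exp(-0.6 * x))
        clin = _clin(time, np.ones(n, dtype=int))
        s1 = ScoreVector(pd.Series(x, index=clin.sample_ids), name="S")
        s2 = ScoreVector(s1.values * 5.0 + 3.0, name="S")
        r1 = fit_cox(pd.DataFrame({"S": s1.values}), clin)
        r2 = fit_cox(pd.DataFrame({"S": s2.values}), clin)
        h1, h2 = hr_iqr(r1, s1), hr_iqr(r2, s2)
        assert h1["hr_iqr"] == pytest.approx(h2["hr_iqr"], rel=1e-6)
        assert h1["ci95_low"] == pytest.approx(h2["ci95_low"], rel=1e-6)

    def test_unknown_covariate_and_zero_iqr_errors(self):
        with pytest.raises(ValidationError, match="not in fitted model"):
            hr_iqr(self._result(0.1, 0.1), self._score([1.0, 2, 3]), covariate="other")
        const = self._score([2.0] * 8)
        with pytest.raises(ValidationError, match="interquartile"):
            hr_iqr(self._result(0.1, 0.1), const)


class TestGrouping:
    def _sv(self, vals, name="S"):
        return ScoreVector(pd.Series(vals, index=[f"s{i}" for i in range(len(vals))]),
                           name=name)

    def test_median_split_examples(self):
        # odd n: the median sample itself goes low
        ga = median_split(self._sv([1.0, 2, 3, 4, 5]))
        assert ga.labels.tolist() == ["low", "low", "low", "high", "high"]
        # even n with ties at the median: ties go low
        ga = median_split(self._sv([1.0, 1, 2, 2]))
        assert ga.labels.tolist() == ["low", "low", "high", "high"]
        assert ga.cutpoints["S"] == pytest.approx(1.5)

    def test_median_split_balance_bound(self):
        rng = np.random.default_rng(21)
        ga = median_split(self._sv(rng.normal(size=101)))
        counts = ga.counts()
        assert counts["high"] <= 50  # strictly-above-median is at most half

    def test_constant_score_is_error(self):
        with pytest.raises(ValidationError, match="constant"):
            median_split(self._sv([3.0, 3.0, 3.0]))

    def test_four_group_composes_from_median_splits(self):
        rng = np.random.default_rng(2)
        emt = self._sv(rng.normal(size=30), name="EMT")
        ita = self._sv(rng.normal(size=30), name="ITA")
        ga = four_group(emt, ita)
        ge, gi = median_split(emt), median_split(ita)
        for s in ga.sample_ids:
            e = "high" if ge.labels[s] == "high" else "low"
            i = "high" if gi.labels[s] == "high" else "low"
            assert ga.labels[s] == f"{e}EMT-{i}ITA"
        assert ga.levels == FOUR_GROUP_LEVELS
        assert ga.counts().sum() == 30

    def test_four_group_comonotone_scores_empty_off_diagonal(self):
        vals = np.arange(20, dtype=float)
        ga = four_group(self._sv(vals, "EMT"), self._sv(vals * 2 + 1, "ITA"))
        counts = ga.counts()
        assert counts["lowEMT-highITA"] == 0 and counts["highEMT-lowITA"] == 0
        assert counts["lowEMT-lowITA"] == counts["highEMT-highITA"] == 10

    def test_four_group_intersects_sample_ids(self):
        emt = self._sv(np.arange(10, dtype=float), "EMT")
        ita = ScoreVector(pd.Series(np.arange(8, dtype=float),
                                    index=[f"s{i}" for i in range(2, 10)]), name="ITA")
        ga = four_group(emt, ita)
        assert ga.sample_ids == [f"s{i}" for i in range(2, 10)]


class TestKaplanMeier:
    def test_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(17)
        n = 50
        time = rng.integers(1, 15, n).astype(float)  # many ties
        event = rng.integers(0, 2, n)
        event[0] = 1
        labels = pd.Series(["all"] * n, index=[f"s{i}" for i in range(n)])
        from itaemt.survival import GroupAssignment

        # two groups required for the log-rank; duplicate as a second group
        time2 = np.concatenate([time, time])
        event2 = np.concatenate([event, event])
        samples = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series(["a"] * n + ["b"] * n, index=samples)
        ga = GroupAssignment(labels=labels, cutpoints={}, levels=["a", "b"])
        curves, chi2, df, p = km_logrank(ga, _clin(time2, event2, samples))
        expected = brute_km(time, event)
        curve = curves["a"]
        got = dict(zip(curve.times, curve.survival))
        for t, s in expected.items():
            assert got[t] == pytest.approx(s, abs=1e-12)
        # identical groups: no difference
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_empty_group_dropped_df_adjusted(self, caplog):
        samples = [f"s{i}" for i in range(20)]
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=samples)
        from itaemt.survival import GroupAssignment

        ga = GroupAssignment(labels=labels, cutpoints={}, levels=["a", "b", "c"])
        rng = np.random.default_rng(1)
        with caplog.at_level("WARNING"):
            _, _, df, _ = km_logrank(
                ga, _clin(rng.exponential(size=20), np.ones(20, dtype=int), samples))
        assert df == 1
        assert any("dropped empty groups" in r.message for r in caplog.records)

    def test_single_group_is_error(self):
        from itaemt.survival import GroupAssignment

        samples = ["s0", "s1", "s2"]
        ga = GroupAssignment(labels=pd.Series(["a"] * 3, index=samples),
                             cutpoints={}, levels=["a"])
        with pytest.raises(ValidationError, match="2 non-empty"):
            km_logrank(ga, _clin([1.0, 2.0, 3.0], [1, 1, 0], samples))


class TestBhAdjust:
    def test_matches_statsmodels_style_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        q = _bh_adjust(p)
        # independent oracle via scipy
        expected = stats.false_discovery_control(p, method="bh")
        assert np.allclose(q, expected, atol=1e-12)

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.8])
        q = _bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()


def _power_setup(seed=31, n=600, n_risk=5, n_null=195, beta=0.6):
    """Expression with a handful of true risk genes among flat nulls."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    z = rng.normal(size=n)  # shared latent driven by the risk genes
    data = {}
    risk_genes = [f"risk{i}" for i in range(n_risk)]
    null_genes = [f"null{i}" for i in range(n_null)]
    for g in risk_genes:
        data[g] = np.maximum(2 ** (5.0 + z + rng.normal(0, 0.3, n)) - 1, 0.0)
    for g in null_genes:
        data[g] = np.maximum(2 ** (5.0 + rng.normal(0, 1.0, n)) - 1, 0.0)
    expr = ExpressionMatrix(pd.DataFrame(data, index=samples).T)
    ita = ScoreVector(pd.Series(rng.normal(size=n), index=samples), name="ITA")
    cov = pd.DataFrame({"z": z, "ita": ita.values.to_numpy()}, index=samples)
    clin = simulate_survival_from_covariates(
        cov, [beta, -0.3], baseline_hazard=5e-4,
        censor_horizon=3650, seed=seed + 1)
    return expr, ita, clin, risk_genes, null_genes


class TestPerGeneCox:
    def test_power_and_null_calibration(self):
        expr, ita, clin, risk_genes, null_genes = _power_setup()
        tab = rank_emt_genes(expr, risk_genes + null_genes, ita, clin)
        tab = tab.set_index("gene")
        assert tab.loc[risk_genes, "selected"].sum() >= 4
        assert tab.loc[risk_genes, "direction"].eq("risk").sum() >= 4
        null_rate = tab.loc[null_genes, "selected"].mean()
        assert null_rate <= 0.10

    def test_sorted_by_p_and_direction_rule(self):
        expr, ita, clin, risk_genes, null_genes = _power_setup(seed=32, n=300,
                                                               n_null=40)
        tab = rank_emt_genes(expr, risk_genes + null_genes, ita, clin)
        p = tab["wald_p"].to_numpy()
        assert (np.diff(p[~np.isnan(p)]) >= 0).all()
        testable = tab[tab["testable"]]
        assert (testable["direction"] == np.where(testable["beta"] > 0,
                                                  "risk", "favorable")).all()
        assert (testable["selected"] == (testable["wald_p"] < 0.05)).all()

    def test_missing_gene_untestable_not_failed(self):
        expr, ita, clin, risk_genes, _ = _power_setup(seed=33, n=200, n_null=10)
        tab = validate_genes(risk_genes + ["absent_gene"], expr, clin, ita)
        row = tab.set_index("gene").loc["absent_gene"]
        assert not row["testable"] and not row["selected"]
        assert np.isnan(row["wald_p"])

    def test_validate_genes_empty_list(self):
        expr, ita, clin, _, _ = _power_setup(seed=34, n=150, n_null=5)
        tab = validate_genes([], expr, clin, ita)
        assert tab.empty and "wald_p" in tab.columns

    def test_validation_replicates_under_same_generative_model(self):
        expr, ita, clin, risk_genes, null_genes = _power_setup(seed=35)
        discovery = rank_emt_genes(expr, risk_genes + null_genes, ita, clin)
        selected = discovery.loc[discovery["selected"], "gene"].tolist()
        expr2, ita2, clin2, _, _ = _power_setup(seed=36)
        rep = validate_genes(selected, expr2, clin2, ita2).set_index("gene")
        assert rep.loc[[g for g in risk_genes if g in rep.index], "selected"].sum() >= 4
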