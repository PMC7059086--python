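"""Estimator families: closed-form examples, brute-force oracles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import synthcohort as sc
from synthcohort.core import Cohort, VariableSpec
from synthcohort.errors import EstimationError, ParameterError
from synthcohort.estimators import (
    MATCHED_SET,
    EstimandSpec,
    estimate_km,
    estimate_odds_ratio,
    estimate_proportion,
    fit_cox,
    fit_logistic_stepwise,
    propensity_match,
    run_estimand,
)

from conftest import make_cohort


def bool_cohort(name, values, extra=()):
    schema = [VariableSpec(name, "boolean", "outcome")] + [v for v, _ in extra]
    cols = {name: values}
    for v, vals in extra:
        cols[v.name] = vals
    return Cohort.from_columns(schema, cols)


def table_cohort(a, b, c, d):
    """2x2 cohort: a=exp&out, b=exp&not, c=unexp&out, d=unexp&not."""
    exp = [True] * (a + b) + [False] * (c + d)
    out = [True] * a + [False] * b + [True] * c + [False] * d
    schema = [VariableSpec("exp", "boolean"), VariableSpec("out", "boolean", "outcome")]
    return Cohort.from_columns(schema, {"exp": exp, "out": out})


OR_SPEC = EstimandSpec(id="or", family="odds_ratio", outcome="out", exposure="exp")


class TestProportion:
    @pytest.mark.parametrize(
        "x,n,point,lo,hi",
        [
            (0, 20, 0.0, 0.0, None),
            (50, 100, 0.5, 0.404, 0.596),  # Wilson closed form at z=1.96
            (20, 20, 1.0, None, 1.0),
        ],
    )
    def test_wilson_interval(self, x, n, point, lo, hi):
        c = bool_cohort("y", [True] * x + [False] * (n - x))
        res = estimate_proportion(c, EstimandSpec(id="p", family="proportion", outcome="y"))
        assert res.point == pytest.approx(point)
        if lo is not None:
            assert res.ci_low == pytest.approx(lo, abs=5e-4)
        if hi is not None:
            assert res.ci_high == pytest.approx(hi, abs=5e-4)
        assert 0.0 <= res.ci_low <= res.point <= res.ci_high <= 1.0

    def test_empty_after_filter_raises(self):
        c = bool_cohort("y", [None, None])
        with pytest.raises(EstimationError):
            estimate_proportion(c, EstimandSpec(id="p", family="proportion", outcome="y"))


class TestOddsRatio:
    def test_symmetric_table_gives_unit_or(self):
        res = estimate_odds_ratio(table_cohort(10, 10, 10, 10), OR_SPEC)
        assert res.point == pytest.approx(0.0)
        assert res.diagnostics["or"] == pytest.approx(1.0)

    def test_known_table(self):
        res = estimate_odds_ratio(table_cohort(20, 10, 10, 20), OR_SPEC)
        assert res.diagnostics["or"] == pytest.approx(4.0)
        assert res.point == pytest.approx(math.log(4.0))
        # Woolf CI: log(4) +/- 1.96 * sqrt(4/20 + 2/10)
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert res.ci_low == pytest.approx(math.log(4) - 1.96 * se, abs=1e-3)
        assert "fisher_p" in res.diagnostics

    def test_zero_cell_gets_haldane_correction(self):
        res = estimate_odds_ratio(table_cohort(0, 10, 10, 10), OR_SPEC)
        assert res.diagnostics.get("haldane_correction") is True
        assert np.isfinite(res.point)

    def test_mantel_haenszel_on_duplicated_strata(self):
        # two identical strata: the MH common OR equals the stratum OR
        base = table_cohort(20, 10, 10, 20)
        strata = ["s1"] * 60 + ["s2"] * 60
        df = pd.concat([base.data, base.data], ignore_index=True)
        df[MATCHED_SET] = strata
        schema = list(base.schema) + [
            VariableSpec(MATCHED_SET, "categorical", "stratum", categories=("s1", "s2"))
        ]
        stratified = Cohort(schema, df)
        res = estimate_odds_ratio(stratified, OR_SPEC)
        assert res.diagnostics["method"] == "mantel_haenszel"
        assert math.exp(res.point) == pytest.approx(4.0)


class TestMatching:
    def _cohort(self, n_exp, n_ctl, rng, shift=0.0):
        x = np.concatenate([rng.normal(shift, 1, n_exp), rng.normal(0, 1, n_ctl)])
        exp = [True] * n_exp + [False] * n_ctl
        out = rng.random(n_exp + n_ctl) < 0.3
        schema = [
            VariableSpec("exp", "boolean"),
            VariableSpec("x", "continuous"),
            VariableSpec("out", "boolean", "outcome"),
        ]
        return Cohort.from_columns(
            schema, {"exp": exp, "x": x, "out": [bool(v) for v in out]}
        )

    SPEC = EstimandSpec(
        id="m",
        family="odds_ratio",
        outcome="out",
        exposure="exp",
        covariates=("x",),
        matching={"method": "nearest_neighbor", "ratio": 4},
    )

    def test_five_exposed_twenty_controls_full_sets(self):
        c = self._cohort(5, 20, np.random.default_rng(1))
        matched, diag = propensity_match(c, self.SPEC, seed=0)
        assert diag["matched_sets"] == 5
        assert diag["control_shortfall"] == 0
        sizes = matched.data.groupby(MATCHED_SET).size()
        assert sizes.tolist() == [5] * 5  # 1 exposed + 4 controls each

    def test_ratio_one_perfect_overlap_matches_everyone(self):
        spec = EstimandSpec(
            id="m1",
            family="odds_ratio",
            outcome="out",
            exposure="exp",
            covariates=("x",),
            matching={"method": "nearest_neighbor", "ratio": 1},
        )
        c = self._cohort(10, 10, np.random.default_rng(2))
        matched, diag = propensity_match(c, spec, seed=3)
        assert diag["matched_sets"] == 10
        assert matched.n == 20

    def test_control_shortfall_recorded(self):
        # 20 controls wanted, only 10 available: all are used, the deficit
        # is recorded, matching never aborts
        c = self._cohort(5, 10, np.random.default_rng(3))
        matched, diag = propensity_match(c, self.SPEC, seed=1)
        assert diag["control_shortfall"] == 10
        n_controls_matched = int((~matched.data["exp"].astype(bool)).sum())
        assert n_controls_matched == 10
        assert 1 <= diag["matched_sets"] <= 5

    def test_perfect_separation_flagged(self):
        c = self._cohort(15, 15, np.random.default_rng(4), shift=60.0)
        _, diag = propensity_match(c, self.SPEC, seed=2)
        assert diag["separation"] is True

    def test_seed_determinism(self):
        c = self._cohort(8, 40, np.random.default_rng(5))
        a, _ = propensity_match(c, self.SPEC, seed=11)
        b, _ = propensity_match(c, self.SPEC, seed=11)
        assert a.equals(b)


def survival_cohort(times, events):
    schema = [
        VariableSpec("t", "continuous", "event_time"),
        VariableSpec("e", "boolean", "event_indicator"),
    ]
    return Cohort.from_columns(schema, {"t": times, "e": events})


KM_SPEC = EstimandSpec(id="km", family="km_survival", time="t", event="e")


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        c = survival_cohort([5.0, 8.0, 2.0, 9.0], [False] * 4)
        res = estimate_km(c, KM_SPEC)
        assert all(s == 1.0 for _, s, _, _ in res.curve)
        assert res.point == 1.0

    def test_single_event_quarter_drop(self):
        c = survival_cohort([2.0, 3.0, 4.0, 5.0], [True, False, False, False])
        res = estimate_km(
            c, EstimandSpec(id="km", family="km_survival", time="t", event="e", horizon=2.0)
        )
        assert res.point == pytest.approx(0.75)

    def test_against_product_limit_oracle(self):
        # brute-force product over risk sets, interleaved censoring, n=10
        times = [1.0, 2.0, 2.5, 3.0, 3.0, 4.0, 5.5, 6.0, 7.0, 8.0]
        events = [True, False, True, True, False, True, False, True, False, False]
        c = survival_cohort(times, events)
        res = estimate_km(c, KM_SPEC)

        def oracle(t):
            s = 1.0
            for u in sorted({tt for tt, ee in zip(times, events) if ee and tt <= t}):
                d = sum(1 for tt, ee in zip(times, events) if ee and tt == u)
                at_risk = sum(1 for tt in times if tt >= u)
                s *= 1 - d / at_risk
            return s

        for t, s, lo, hi in res.curve:
            assert s == pytest.approx(oracle(t), abs=1e-12)
            assert 0.0 <= lo <= s <= hi <= 1.0

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(8)
        c = survival_cohort(
            rng.exponential(10, 50).tolist(), (rng.random(50) < 0.7).tolist()
        )
        res = estimate_km(c, KM_SPEC)
        surv = [s for _, s, _, _ in res.curve]
        assert all(a >= b for a, b in zip(surv, surv[1:]))


def cox_cohort(rng, n, beta, p_exposed=0.5):
    x = rng.random(n) < p_exposed
    t = rng.exponential(1.0, n) / np.exp(beta * x)
    horizon = np.quantile(t, 0.8)
    schema = [
        VariableSpec("x", "boolean"),
        VariableSpec("t", "continuous", "event_time"),
        VariableSpec("e", "boolean", "event_indicator"),
    ]
    return Cohort.from_columns(
        schema,
        {
            "x": [bool(v) for v in x],
            "t": np.minimum(t, horizon),
            "e": [bool(v) for v in t <= horizon],
        },
    )


COX_SPEC = EstimandSpec(id="cox", family="cox_hr", time="t", event="e", covariates=("x",))


class TestCox:
    def test_against_partial_likelihood_grid_oracle(self):
        # single binary covariate, no ties: the Breslow/Efron partial
        # likelihood coincides and can be maximized directly
        c = cox_cohort(np.random.default_rng(12), 30, beta=0.7)
        (res,) = fit_cox(c, COX_SPEC)

        t = c.data["t"].astype(float).to_numpy()
        e = c.data["e"].astype(bool).to_numpy()
        x = c.data["x"].astype(bool).to_numpy().astype(float)
        assert len(np.unique(t[e])) == e.sum()  # no tied event times

        def neg_log_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(e):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        opt = optimize.minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert res.point == pytest.approx(opt.x, abs=1e-4)

    def test_duplicated_cohort_same_point_narrower_ci(self):
        # the partial-likelihood maximizer is invariant under duplication up
        # to Efron's tie adjustment (duplication ties every event time)
        c = cox_cohort(np.random.default_rng(13), 80, beta=0.5)
        doubled = Cohort(
            c.schema, pd.concat([c.data, c.data], ignore_index=True)
        )
        (r1,) = fit_cox(c, COX_SPEC)
        (r2,) = fit_cox(doubled, COX_SPEC)
        assert r2.point == pytest.approx(r1.point, abs=0.02)
        assert (r2.ci_high - r2.ci_low) < (r1.ci_high - r1.ci_low)

    def test_categorical_covariate_reference_dummies(self):
        c = sc.simulate(sc.make_preset("bun_adhf", n=1500, seed=6))
        spec = EstimandSpec(
            id="c", family="cox_hr", time="time_to_event", event="event",
            covariates=("bun_cat",),
        )
        results = fit_cox(c, spec)
        ids = {r.estimand_id for r in results}
        assert ids == {"c:bun_cat[30to39]", "c:bun_cat[ge40]"}  # lt30 is reference

    def test_no_events_raises(self):
        c = survival_cohort([1.0, 2.0], [False, False])
        spec = EstimandSpec(id="c", family="cox_hr", time="t", event="e", covariates=())
        with pytest.raises(EstimationError):
            fit_cox(c, spec)


class TestStepwiseLogistic:
    def test_pure_noise_keeps_nearly_nothing(self):
        rng = np.random.default_rng(30)
        n = 2000
        schema = [
            VariableSpec("y", "boolean", "outcome"),
            VariableSpec("a", "continuous"),
            VariableSpec("b", "continuous"),
            VariableSpec("d", "boolean"),
        ]
        c = Cohort.from_columns(
            schema,
            {
                "y": [bool(v) for v in rng.random(n) < 0.3],
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "d": [bool(v) for v in rng.random(n) < 0.5],
            },
        )
        spec = EstimandSpec(
            id="s", family="logistic_risk", outcome="y", covariates=("a", "b", "d"),
            risk_profile={"a": 0.0, "b": 0.0, "d": False},
        )
        desc, res = fit_logistic_stepwise(c, spec)
        assert len(desc["terms"]) <= 2  # drops most noise terms
        # every accepted move improved AIC
        aics = [step["aic"] for step in desc["trace"]]
        assert all(x > y for x, y in zip(aics, aics[1:])) or len(aics) <= 1
        assert 0.0 <= res.point <= 1.0

    def test_interaction_recovery(self):
        # logit p = -1 + 1.5*drug - 0.8*albumin - 1.2*drug*albumin on a
        # unit-scale covariate, n = 20,000: stepwise keeps the interaction
        # and the refitted coefficients land within +/-0.15 of truth
        overrides = {
            "albumin_mean": 0.0,
            "albumin_sd": 1.0,
            "albumin_range": (-4.0, 4.0),
            "coef": {"intercept": -1.0, "drug": 1.5, "albumin": -0.8, "interaction": -1.2},
        }
        c = sc.simulate(
            sc.make_preset("insulin_hypoglycemia", n=20_000, seed=31, overrides=overrides)
        )
        spec = EstimandSpec(
            id="s", family="logistic_risk", outcome="hypoglycemia",
            covariates=("detemir", "albumin", "dose_per_kg"),
            risk_profile={"detemir": True, "albumin": -1.0, "dose_per_kg": 0.5},
        )
        desc, _ = fit_logistic_stepwise(c, spec)
        assert "detemir:albumin" in desc["terms"]

        import statsmodels.formula.api as smf
        from statsmodels.genmod.families import Binomial

        d = pd.DataFrame(
            {
                "y": c.data["hypoglycemia"].astype(bool).astype(int),
                "drug": c.data["detemir"].astype(bool).astype(int),
                "alb": c.data["albumin"].astype(float),
            }
        )
        fit = smf.glm("y ~ drug + alb + drug:alb", d, family=Binomial()).fit()
        truth = {"Intercept": -1.0, "drug": 1.5, "alb": -0.8, "drug:alb": -1.2}
        for name, true_val in truth.items():
            assert fit.params[name] == pytest.approx(true_val, abs=0.15)

    def test_risk_profile_at_crossing_point(self):
        # drug effect 1.5 - 1.2*(albumin-3.5) vanishes at albumin = 4.75:
        # the two drugs' predicted risks agree within their CIs there
        c = sc.simulate(sc.make_preset("insulin_hypoglycemia", n=20_000, seed=32))
        results = {}
        for drug in (True, False):
            spec = EstimandSpec(
                id=f"r{drug}", family="logistic_risk", outcome="hypoglycemia",
                covariates=("detemir", "albumin"),
                risk_profile={"detemir": drug, "albumin": 4.75},
            )
            _, results[drug] = fit_logistic_stepwise(c, spec)
        lo = max(results[True].ci_low, results[False].ci_low)
        hi = min(results[True].ci_high, results[False].ci_high)
        assert lo <= hi  # intervals overlap

    def test_empty_profile_rejected(self):
        c = sc.simulate(sc.make_preset("insulin_hypoglycemia", n=500, seed=33))
        spec = EstimandSpec(
            id="s", family="logistic_risk", outcome="hypoglycemia",
            covariates=("detemir",), risk_profile=None,
        )
        with pytest.raises(ParameterError):
            fit_logistic_stepwise(c, spec)


class TestDispatch:
    def test_unknown_variable_names_offender(self):
        c = table_cohort(5, 5, 5, 5)
        spec = EstimandSpec(id="p", family="proportion", outcome="nope")
        with pytest.raises(sc.SchemaError, match="nope"):
            run_estimand(c, spec)

    def test_scale_ordering_preserved_under_exponentiation(self):
        res = estimate_odds_ratio(table_cohort(20, 10, 10, 20), OR_SPEC)
        assert math.exp(res.ci_low) <= math.exp(res.point) <= math.exp(res.ci_high)
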