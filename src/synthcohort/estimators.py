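"""Analytic adapters run on real and synthetic cohorts.

One estimator family per study design the validation protocol covers:

* ``proportion`` — subgroup proportion with a Wilson score interval.
* ``odds_ratio`` — 2×2 exposure-outcome odds ratio; Woolf logit CI and
  Fisher exact p unmatched, Mantel–Haenszel common OR with the
  Robins–Breslow–Greenland CI on matched (stratified) data.
* ``km_survival`` — Kaplan–Meier product-limit curve with a Greenwood
  log–log 95% band; the point estimate is survival at a horizon.
* ``cox_hr`` — multivariate Cox proportional hazards (Efron ties), one
  result per coefficient.
* ``logistic_risk`` — logistic regression over main effects and pairwise
  interactions selected by bidirectional AIC stepwise (interaction
  hierarchy enforced), reporting the predicted risk at a covariate profile
  with a delta-method CI.

Log-scale estimands (odds and hazard ratios) are reported on the log scale,
where their sampling distributions are near-symmetric; the ratio itself is
carried in ``diagnostics``. All estimators use complete-case analysis over
the variables they touch (imputation is left to the analyst, exactly as
with real data) and are deterministic given their inputs; propensity
matching is the only seeded operation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort, VariableSpec
from .errors import EstimationError, ParameterError, SchemaError

FAMILIES = ("proportion", "odds_ratio", "km_survival", "cox_hr", "logistic_risk")
SCALES = ("proportion", "log_odds_ratio", "log_hazard_ratio", "risk")

MATCHED_SET = "matched_set"


@dataclass(frozen=True)
class EstimandSpec:
    """Declarative description of one analysis target."""

    id: str
    family: str
    outcome: str | None = None
    group: str | None = None
    group_level: object = None
    exposure: str | None = None
    covariates: tuple[str, ...] = ()
    time: str | None = None
    event: str | None = None
    horizon: float | None = None
    matching: Mapping | None = None  # {"method": "nearest_neighbor", "ratio": int}
    risk_profile: Mapping | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown estimator family {self.family!r}")
        if self.matching is not None:
            ratio = int(self.matching.get("ratio", 1))
            if ratio < 1:
                raise ParameterError("matching ratio must be ≥ 1")

    def to_dict(self) -> dict:
        d: dict = {"id": self.id, "family": self.family}
        for key in (
            "outcome",
            "group",
            "group_level",
            "exposure",
            "time",
            "event",
            "horizon",
        ):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        if self.covariates:
            d["covariates"] = list(self.covariates)
        if self.matching is not None:
            d["matching"] = dict(self.matching)
        if self.risk_profile is not None:
            d["risk_profile"] = dict(self.risk_profile)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EstimandSpec":
        return cls(
            id=str(d["id"]),
            family=str(d["family"]),
            outcome=d.get("outcome"),
            group=d.get("group"),
            group_level=d.get("group_level"),
            exposure=d.get("exposure"),
            covariates=tuple(d.get("covariates", ())),
            time=d.get("time"),
            event=d.get("event"),
            horizon=d.get("horizon"),
            matching=d.get("matching"),
            risk_profile=d.get("risk_profile"),
        )

    def validate_against(self, schema: Sequence[VariableSpec]) -> None:
        """Check that every referenced variable exists with a usable kind."""
        by_name = {v.name: v for v in schema}

        def need(name: str | None, kinds: tuple[str, ...], what: str) -> None:
            if name is None:
                return
            if name not in by_name:
                raise SchemaError(
                    f"estimand {self.id!r}: {what} variable {name!r} not in schema"
                )
            if by_name[name].kind not in kinds:
                raise SchemaError(
                    f"estimand {self.id!r}: {what} variable {name!r} has kind "
                    f"{by_name[name].kind}, expected one of {kinds}"
                )

        if self.family == "proportion":
            need(self.outcome, ("boolean",), "outcome")
        elif self.family == "odds_ratio":
            need(self.outcome, ("boolean",), "outcome")
            need(self.exposure, ("boolean",), "exposure")
        elif self.family == "km_survival":
            need(self.time, ("continuous",), "time")
            need(self.event, ("boolean",), "event")
        elif self.family == "cox_hr":
            need(self.time, ("continuous",), "time")
            need(self.event, ("boolean",), "event")
        elif self.family == "logistic_risk":
            need(self.outcome, ("boolean",), "outcome")
        need(self.group, ("categorical", "boolean"), "group")
        for c in self.covariates:
            need(c, ("categorical", "boolean", "continuous"), "covariate")


@dataclass
class EstimateResult:
    """Point estimate with a 95% interval on a declared scale."""

    estimand_id: str
    point: float
    ci_low: float
    ci_high: float
    scale: str
    curve: list[tuple[float, float, float, float]] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ParameterError(f"unknown scale {self.scale!r}")
        eps = 1e-9
        if not (self.ci_low - eps <= self.point <= self.ci_high + eps):
            raise EstimationError(
                f"{self.estimand_id}: interval ({self.ci_low}, {self.ci_high}) "
                f"does not bracket point {self.point}"
            )

    def to_dict(self) -> dict:
        d = {
            "estimand_id": self.estimand_id,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "scale": self.scale,
            "diagnostics": _jsonable(self.diagnostics),
        }
        if self.curve is not None:
            d["curve"] = [list(pt) for pt in self.curve]
        return d


def _jsonable(d: Mapping) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            out[k] = int(v)
        elif isinstance(v, (np.floating,)):
            out[k] = float(v)
        elif isinstance(v, np.bool_):
            out[k] = bool(v)
        else:
            out[k] = v
    return out


def _apply_group_filter(cohort: Cohort, spec: EstimandSpec) -> Cohort:
    if spec.group is None or spec.group_level is None:
        return cohort
    col = cohort.data[spec.group]
    mask = (~col.isna()).to_numpy() & (col == spec.group_level).fillna(False).to_numpy()
    return cohort.subset(mask)


# ---------------------------------------------------------------------------
# proportion
# ---------------------------------------------------------------------------


def estimate_proportion(cohort: Cohort, spec: EstimandSpec) -> EstimateResult:
    """Proportion of true outcomes with a Wilson score 95% interval."""
    from statsmodels.stats.proportion import proportion_confint

    cohort = _apply_group_filter(cohort, spec)
    col = cohort.data[spec.outcome]
    obs = col[~col.isna()].astype(bool)
    n = len(obs)
    if n == 0:
        raise EstimationError(f"{spec.id}: no non-missing outcomes to estimate from")
    x = int(obs.sum())
    lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    point = x / n
    return EstimateResult(
        estimand_id=spec.id,
        point=point,
        ci_low=min(float(lo), point),  # guard float round-off at the boundaries
        ci_high=max(float(hi), point),
        scale="proportion",
        diagnostics={"n": n, "successes": x},
    )


# ---------------------------------------------------------------------------
# odds ratio (Fisher / Woolf unmatched, Mantel–Haenszel matched)
# ---------------------------------------------------------------------------


def _two_by_two(df: pd.DataFrame, exposure: str, outcome: str) -> np.ndarray:
    e = df[exposure].astype(bool).to_numpy()
    y = df[outcome].astype(bool).to_numpy()
    return np.array(
        [
            [int((e & y).sum()), int((e & ~y).sum())],
            [int((~e & y).sum()), int((~e & ~y).sum())],
        ],
        dtype=float,
    )


def estimate_odds_ratio(cohort: Cohort, spec: EstimandSpec) -> EstimateResult:
    """Exposure–outcome odds ratio, reported on the log scale.

    If the cohort carries a ``matched_set`` stratum variable (produced by
    :func:`propensity_match`), the Mantel–Haenszel common OR over matched
    sets with the Robins–Breslow–Greenland CI is used; otherwise the crude
    sample OR with the Woolf logit CI and a Fisher exact p-value.
    """
    cohort = _apply_group_filter(cohort, spec)
    used = [spec.exposure, spec.outcome]
    stratified = any(v.name == MATCHED_SET for v in cohort.schema)
    if stratified:
        used.append(MATCHED_SET)
    df = cohort.data[used].dropna()
    if len(df) == 0:
        raise EstimationError(f"{spec.id}: no complete cases")

    diagnostics: dict = {"n": len(df)}
    if stratified:
        from statsmodels.stats.contingency_tables import StratifiedTable

        tables = []
        for _, sub in df.groupby(MATCHED_SET, sort=True):
            tables.append(_two_by_two(sub, spec.exposure, spec.outcome))
        st = StratifiedTable(np.dstack(tables))
        or_mh = float(st.oddsratio_pooled)
        lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
        if not (np.isfinite(or_mh) and or_mh > 0 and np.isfinite(lo) and np.isfinite(hi)):
            raise EstimationError(f"{spec.id}: Mantel–Haenszel OR degenerate")
        diagnostics.update({"method": "mantel_haenszel", "strata": len(tables), "or": or_mh})
        return EstimateResult(
            estimand_id=spec.id,
            point=math.log(or_mh),
            ci_low=math.log(float(lo)),
            ci_high=math.log(float(hi)),
            scale="log_odds_ratio",
            diagnostics=diagnostics,
        )

    tab = _two_by_two(df, spec.exposure, spec.outcome)
    a, b = tab[0]
    c, d = tab[1]
    diagnostics["fisher_p"] = float(stats.fisher_exact(tab.astype(int))[1])
    if min(a, b, c, d) == 0:
        # Haldane–Anscombe continuity correction for empty cells
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        diagnostics["haldane_correction"] = True
    or_hat = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)  # Woolf
    log_or = math.log(or_hat)
    diagnostics.update({"method": "woolf", "or": or_hat, "table": tab.astype(int).tolist()})
    return EstimateResult(
        estimand_id=spec.id,
        point=log_or,
        ci_low=log_or - 1.959963984540054 * se,
        ci_high=log_or + 1.959963984540054 * se,
        scale="log_odds_ratio",
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# propensity-score matching
# ---------------------------------------------------------------------------


def _design_matrix(cohort: Cohort, names: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Numeric design columns: booleans as 0/1, categoricals as reference dummies."""
    cols: dict[str, pd.Series] = {}
    for nm in names:
        var = cohort.variable(nm)
        col = cohort.data[nm]
        if var.kind == "continuous":
            cols[nm] = col.astype(float)
        elif var.kind == "boolean":
            cols[nm] = col.map({True: 1.0, False: 0.0}).astype(float)
        else:
            for level in var.categories[1:]:
                cols[f"{nm}[{level}]"] = col.map(
                    lambda v, lv=level: np.nan if pd.isna(v) else float(v == lv)
                ).astype(float)
    df = pd.DataFrame(cols)
    return df, list(df.columns)


def propensity_match(
    cohort: Cohort, spec: EstimandSpec, seed: int
) -> tuple[Cohort, dict]:
    """Greedy 1:ratio nearest-neighbor matching on the propensity logit.

    The propensity model is a logistic regression of exposure on the spec's
    covariates. Exposed records are processed in random order (``seed``);
    each takes its ``ratio`` nearest unmatched controls, without
    replacement. Returns the matched cohort extended with a ``matched_set``
    stratum variable, plus diagnostics (matched-set count, control
    shortfall, separation flag).
    """
    from sklearn.linear_model import LogisticRegression

    if spec.matching is None:
        raise ParameterError(f"estimand {spec.id!r} has no matching specification")
    ratio = int(spec.matching.get("ratio", 1))
    used = [spec.exposure, *spec.covariates]
    mask = ~cohort.data[used].isna().any(axis=1)
    sub = cohort.subset(mask.to_numpy())
    X, _ = _design_matrix(sub, spec.covariates)
    y = sub.data[spec.exposure].astype(bool).to_numpy()
    if y.sum() == 0 or (~y).sum() == 0:
        raise EstimationError(f"{spec.id}: one exposure arm is empty")

    # C=inf ⇒ unpenalized maximum-likelihood propensity model
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    lr.fit(X.to_numpy(), y.astype(int))
    logit = X.to_numpy() @ lr.coef_[0] + lr.intercept_[0]

    exp_idx = np.flatnonzero(y)
    ctl_idx = np.flatnonzero(~y)
    separation = (
        logit[exp_idx].min() > logit[ctl_idx].max()
        or logit[exp_idx].max() < logit[ctl_idx].min()
    )

    order = np.random.default_rng(seed).permutation(len(exp_idx))
    ctl_sorted = ctl_idx[np.argsort(logit[ctl_idx], kind="stable")]
    ctl_logit = logit[ctl_sorted]
    used_ctl = np.zeros(len(ctl_sorted), dtype=bool)

    set_labels = np.full(sub.n, -1, dtype=int)
    shortfall = 0
    n_sets = 0
    for set_id, k in enumerate(order):
        i = exp_idx[k]
        target = logit[i]
        picks = []
        pos = int(np.searchsorted(ctl_logit, target))
        left, right = pos - 1, pos
        while len(picks) < ratio and (left >= 0 or right < len(ctl_sorted)):
            # advance each pointer past exhausted controls
            while left >= 0 and used_ctl[left]:
                left -= 1
            while right < len(ctl_sorted) and used_ctl[right]:
                right += 1
            dl = target - ctl_logit[left] if left >= 0 else np.inf
            dr = ctl_logit[right] - target if right < len(ctl_sorted) else np.inf
            if not np.isfinite(dl) and not np.isfinite(dr):
                break
            if dl <= dr:
                picks.append(left)
                used_ctl[left] = True
                left -= 1
            else:
                picks.append(right)
                used_ctl[right] = True
                right += 1
        if not picks:
            shortfall += ratio
            continue
        shortfall += ratio - len(picks)
        set_labels[i] = set_id
        for p in picks:
            set_labels[ctl_sorted[p]] = set_id
        n_sets += 1

    keep = set_labels >= 0
    width = max(4, len(str(max(n_sets, 1))))
    labels = [f"s{lab:0{width}d}" if lab >= 0 else None for lab in set_labels]
    categories = tuple(sorted({l for l in labels if l is not None}))
    schema = list(sub.schema) + [
        VariableSpec(MATCHED_SET, "categorical", "stratum", categories=categories)
    ]
    df = sub.data.copy()
    df[MATCHED_SET] = pd.Series(labels, dtype="object")
    matched = Cohort(schema, df.loc[keep].reset_index(drop=True))
    diagnostics = {
        "n_exposed": int(y.sum()),
        "n_controls": int((~y).sum()),
        "matched_sets": n_sets,
        "ratio": ratio,
        "control_shortfall": int(shortfall),
        "separation": bool(separation),
    }
    return matched, diagnostics


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


def _step_lookup(times: np.ndarray, values: np.ndarray, t: float, before: float) -> float:
    idx = np.searchsorted(times, t, side="right") - 1
    return float(values[idx]) if idx >= 0 else before


def estimate_km(cohort: Cohort, spec: EstimandSpec) -> EstimateResult:
    """Product-limit survival curve with a Greenwood log–log 95% band."""
    from lifelines import KaplanMeierFitter

    cohort = _apply_group_filter(cohort, spec)
    df = cohort.data[[spec.time, spec.event]].dropna()
    if len(df) == 0:
        raise EstimationError(f"{spec.id}: no complete cases for survival")
    durations = df[spec.time].astype(float).to_numpy()
    events = df[spec.event].astype(bool).to_numpy()

    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)
    curve = [(float(t), float(s), float(l), float(h)) for t, s, l, h in zip(times, surv, lo, hi)]

    horizon = spec.horizon if spec.horizon is not None else float(durations.max())
    point = _step_lookup(times, surv, horizon, 1.0)
    ci_low = _step_lookup(times, lo, horizon, 1.0)
    ci_high = _step_lookup(times, hi, horizon, 1.0)
    return EstimateResult(
        estimand_id=spec.id,
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        scale="proportion",
        curve=curve,
        diagnostics={"n": len(df), "events": int(events.sum()), "horizon": float(horizon)},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def fit_cox(cohort: Cohort, spec: EstimandSpec) -> list[EstimateResult]:
    """Multivariate Cox PH fit (Efron ties); one result per coefficient.

    Point and interval are on the log-hazard-ratio scale; the hazard ratio
    itself sits in diagnostics along with events and concordance.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cohort = _apply_group_filter(cohort, spec)
    used = [spec.time, spec.event, *spec.covariates]
    mask = ~cohort.data[used].isna().any(axis=1)
    sub = cohort.subset(mask.to_numpy())
    if sub.n == 0:
        raise EstimationError(f"{spec.id}: no complete cases")
    X, colnames = _design_matrix(sub, spec.covariates)
    X = X.copy()
    X["__time__"] = sub.data[spec.time].astype(float)
    X["__event__"] = sub.data[spec.event].astype(bool).astype(int)
    n_events = int(X["__event__"].sum())
    if n_events == 0:
        raise EstimationError(f"{spec.id}: no events observed")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="__time__", event_col="__event__")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise EstimationError(
            f"{spec.id}: Cox fit failed over covariates {list(colnames)} ({exc})"
        ) from None

    ci = cph.confidence_intervals_
    results = []
    for col in colnames:
        beta = float(cph.params_[col])
        lo = float(ci.loc[col].iloc[0])
        hi = float(ci.loc[col].iloc[1])
        results.append(
            EstimateResult(
                estimand_id=f"{spec.id}:{col}",
                point=beta,
                ci_low=lo,
                ci_high=hi,
                scale="log_hazard_ratio",
                diagnostics={
                    "n": sub.n,
                    "events": n_events,
                    "hr": math.exp(beta),
                    "concordance": float(cph.concordance_index_),
                },
            )
        )
    return results


# ---------------------------------------------------------------------------
# AIC-stepwise logistic regression with interaction hierarchy
# ---------------------------------------------------------------------------


def _term_expr(cohort: Cohort, name: str) -> str:
    return f"C({name})" if cohort.variable(name).kind == "categorical" else name


def _fit_glm(df: pd.DataFrame, outcome: str, terms: Sequence[str]):
    import statsmodels.formula.api as smf
    from statsmodels.genmod.families import Binomial

    rhs = " + ".join(terms) if terms else "1"
    return smf.glm(f"{outcome} ~ {rhs}", data=df, family=Binomial()).fit()


def fit_logistic_stepwise(
    cohort: Cohort, spec: EstimandSpec
) -> tuple[dict, EstimateResult]:
    """Bidirectional AIC stepwise from the main-effects logistic model.

    The candidate scope is all main effects of ``spec.covariates`` plus all
    their pairwise interactions; an interaction may enter only while both
    mains are present, and a main may leave only when no retained
    interaction uses it. Returns the selected-model description and the
    predicted risk (with delta-method 95% CI) at ``spec.risk_profile``.
    """
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if not spec.risk_profile:
        raise ParameterError(f"estimand {spec.id!r}: risk_profile must be non-empty")
    cohort = _apply_group_filter(cohort, spec)
    used = [spec.outcome, *spec.covariates]
    mask = ~cohort.data[used].isna().any(axis=1)
    sub = cohort.subset(mask.to_numpy())
    if sub.n == 0:
        raise EstimationError(f"{spec.id}: no complete cases")

    df = pd.DataFrame(index=range(sub.n))
    df[spec.outcome] = sub.data[spec.outcome].astype(bool).astype(int).to_numpy()
    for nm in spec.covariates:
        var = sub.variable(nm)
        if var.kind == "continuous":
            df[nm] = sub.data[nm].astype(float).to_numpy()
        elif var.kind == "boolean":
            df[nm] = sub.data[nm].astype(bool).astype(int).to_numpy()
        else:
            df[nm] = sub.data[nm].astype(str).to_numpy()

    mains = [_term_expr(sub, nm) for nm in spec.covariates]
    interactions = [f"{a}:{b}" for a, b in itertools.combinations(mains, 2)]
    current = list(mains)
    cache: dict[frozenset, float] = {}

    def aic_of(terms: Sequence[str]) -> float:
        key = frozenset(terms)
        if key not in cache:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cache[key] = float(_fit_glm(df, spec.outcome, terms).aic)
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                raise EstimationError(f"{spec.id}: separation in logistic fit ({exc})") from None
        return cache[key]

    trace = []
    best_aic = aic_of(current)
    for _ in range(2 * (len(mains) + len(interactions)) + 4):
        moves: list[tuple[str, str, list[str]]] = []
        cur = set(current)
        for t in interactions:
            a, b = t.split(":")
            if t not in cur and a in cur and b in cur:
                moves.append(("add", t, current + [t]))
        for t in list(current):
            if ":" in t:
                moves.append(("drop", t, [u for u in current if u != t]))
            else:
                if not any(":" in u and t in u.split(":") for u in current):
                    moves.append(("drop", t, [u for u in current if u != t]))
        scored = [(aic_of(terms), action, t, terms) for action, t, terms in moves]
        if not scored:
            break
        scored.sort(key=lambda s: (s[0], s[1], s[2]))
        aic, action, term, terms = scored[0]
        if aic >= best_aic - 1e-9:
            break
        trace.append({"action": action, "term": term, "aic": aic})
        current, best_aic = terms, aic

    final = _fit_glm(df, spec.outcome, current)
    prof = pd.DataFrame({k: [v] for k, v in spec.risk_profile.items()})
    for nm in spec.covariates:
        if nm in prof.columns:
            var = sub.variable(nm)
            if var.kind == "continuous":
                prof[nm] = prof[nm].astype(float)
            elif var.kind == "boolean":
                prof[nm] = prof[nm].astype(bool).astype(int)
            else:
                prof[nm] = prof[nm].astype(str)
    needed = {nm for t in current for nm in t.replace("C(", "").replace(")", "").split(":")}
    missing_prof = needed - set(prof.columns)
    if missing_prof:
        raise ParameterError(
            f"estimand {spec.id!r}: risk_profile lacks values for {sorted(missing_prof)}"
        )
    pred = final.get_prediction(prof).summary_frame(alpha=0.05)
    point = float(pred["mean"].iloc[0])
    ci_low = float(pred["mean_ci_lower"].iloc[0])
    ci_high = float(pred["mean_ci_upper"].iloc[0])

    description = {
        "terms": list(current),
        "aic": best_aic,
        "params": {k: float(v) for k, v in final.params.items()},
        "trace": trace,
    }
    result = EstimateResult(
        estimand_id=spec.id,
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        scale="risk",
        diagnostics={"n": sub.n, "terms": list(current), "aic": best_aic},
    )
    return description, result


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def run_estimand(cohort: Cohort, spec: EstimandSpec, seed: int = 0) -> list[EstimateResult]:
    """Run one estimand on a cohort; always returns a list of results.

    Propensity matching, when requested by the spec, is applied before the
    odds-ratio estimator; ``seed`` feeds only the matching order.
    """
    spec.validate_against(cohort.schema)
    if spec.family == "proportion":
        return [estimate_proportion(cohort, spec)]
    if spec.family == "odds_ratio":
        if spec.matching is not None:
            matched, diag = propensity_match(cohort, spec, seed)
            res = estimate_odds_ratio(matched, spec)
            res.diagnostics.update({f"matching_{k}": v for k, v in diag.items()})
            return [res]
        return [estimate_odds_ratio(cohort, spec)]
    if spec.family == "km_survival":
        return [estimate_km(cohort, spec)]
    if spec.family == "cox_hr":
        return fit_cox(cohort, spec)
    if spec.family == "logistic_risk":
        _, res = fit_logistic_stepwise(cohort, spec)
        return [res]
    raise ParameterError(f"unknown family {spec.family!r}")
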