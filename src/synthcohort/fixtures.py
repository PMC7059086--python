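"""Seeded simulators of "real" cohorts with known ground truth.

Real hospital extracts behind the five archetypal study designs are not
shareable, so these generators produce cohorts with the same statistical
skeletons at configurable size, making the whole pipeline testable without
any data download:

* ``ppi_prescription`` — subgroup proportions with a binary outcome
  (prescription-omission style; heavy subgroup size imbalance).
* ``pci_stemi`` / ``bun_adhf`` — proportional-hazards survival with boolean
  and categorical covariates (door-to-balloon exposure; thresholded-lab
  categories with hazard ratios near 1.29 and 1.67, three-year survival
  stepping roughly 60/44/37% across categories) under administrative
  censoring at a fixed horizon.
* ``imaging_aki`` — a 2×2 exposure–outcome contingency with boolean
  confounders and a ~700-vs-12,600 group imbalance, for propensity-matched
  odds ratios.
* ``insulin_hypoglycemia`` — a logistic outcome with a drug × albumin
  interaction whose sign makes the drug riskier at low albumin.

Default sizes and effect magnitudes echo the printed magnitudes of the
archetypes; they are shape choices, not reproduction claims. Every cohort
is fully determined by ``(preset, seed)``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import Cohort, VariableSpec
from .errors import ParameterError

PRESET_NAMES = (
    "ppi_prescription",
    "pci_stemi",
    "bun_adhf",
    "imaging_aki",
    "insulin_hypoglycemia",
)

_DEFAULTS: dict[str, dict] = {
    "ppi_prescription": {
        # subgroup sizes mirror an anticoagulant cohort's antiplatelet split
        "subgroups": {
            "oac_aspirin": {"n": 3953, "p": 0.62},
            "oac_p2y12": {"n": 882, "p": 0.55},
            "oac_dat": {"n": 417, "p": 0.48},
        }
    },
    "pci_stemi": {
        "n": 597,
        "prevalence": {
            "d2b_gt90": 0.35,
            "age_gt65": 0.50,
            "male": 0.72,
            "severe_cardiac": 0.10,
            "prior_ihd": 0.25,
            "low_hemoglobin": 0.15,
            "high_creatinine": 0.30,
            "high_bun": 0.20,
        },
        "log_hazards": {
            "d2b_gt90": 0.0,  # guideline-compliant timing shows no added risk
            "age_gt65": 0.69,
            "male": 0.10,
            "severe_cardiac": 0.92,
            "prior_ihd": 0.26,
            "low_hemoglobin": 0.30,
            "high_creatinine": 0.30,
            "high_bun": 0.41,
        },
        "weibull_shape": 1.0,
        "weibull_scale": 1700.0,
        "horizon": 180.0,
    },
    "bun_adhf": {
        "n": 4590,
        "category_var": "bun_cat",
        "category_levels": {"lt30": 0.55, "30to39": 0.25, "ge40": 0.20},
        "category_log_hazards": {"30to39": math.log(1.29), "ge40": math.log(1.67)},
        "prevalence": {"high_bnp": 0.40, "high_rdw": 0.30, "low_sodium": 0.20},
        "log_hazards": {"high_bnp": 0.262, "high_rdw": 0.182, "low_sodium": 0.223},
        "weibull_shape": 1.0,
        "weibull_scale": 2600.0,
        "horizon": 1095.0,
    },
    "imaging_aki": {
        "groups": {
            "mri": {"n": 718, "base_logit": -3.9},
            "ct": {"n": 12592, "base_logit": -3.3},
        },
        "confounders": {
            "age_gt65": {"mri": 0.45, "ct": 0.55, "log_or": 0.7},
            "diabetes": {"mri": 0.15, "ct": 0.25, "log_or": 0.5},
            "high_creatinine": {"mri": 0.15, "ct": 0.20, "log_or": 0.9},
        },
    },
    "insulin_hypoglycemia": {
        "n": 4677,
        "p_drug": 0.1778,
        "albumin_mean": 3.5,
        "albumin_sd": 0.5,
        "albumin_range": (1.8, 5.2),
        "dose_mean": 0.5,
        "dose_sd": 0.15,
        # slopes act on albumin centered at its mean (g/dL)
        "coef": {"intercept": -3.0, "drug": 1.5, "albumin": -0.8, "interaction": -1.2, "dose": 0.0},
    },
}


@dataclass(frozen=True)
class FixturePreset:
    """A named generative archetype with its true parameters and seed."""

    name: str
    n: int | None
    true_params: Mapping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in PRESET_NAMES:
            raise ParameterError(f"unknown preset {self.name!r}")
        if self.n is not None and self.n < 1:
            raise ParameterError("n must be ≥ 1")
        for key in ("weibull_shape", "weibull_scale"):
            v = self.true_params.get(key)
            if v is not None and v <= 0:
                raise ParameterError(f"{key} must be positive")

        for sub in self.true_params.get("subgroups", {}).values():
            if not 0 <= sub["p"] <= 1:
                raise ParameterError("subgroup probabilities must lie in [0, 1]")
        for prob in self.true_params.get("prevalence", {}).values():
            if not 0 <= prob <= 1:
                raise ParameterError("prevalences must lie in [0, 1]")


def _merge(base: dict, overrides: Mapping | None) -> dict:
    out = copy.deepcopy(base)
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, Mapping) and isinstance(out.get(k), dict):
                out[k] = _merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
    return out


def make_preset(
    name: str, n: int | None = None, seed: int = 0, overrides: Mapping | None = None
) -> FixturePreset:
    """Build a preset from its defaults, optionally rescaled to ``n`` records."""
    if name not in _DEFAULTS:
        raise ParameterError(f"unknown preset {name!r}")
    params = _merge(_DEFAULTS[name], overrides)
    if n is not None:
        if name == "ppi_prescription":
            total = sum(s["n"] for s in params["subgroups"].values())
            for s in params["subgroups"].values():
                s["n"] = max(1, round(s["n"] * n / total))
        elif name == "imaging_aki":
            total = sum(g["n"] for g in params["groups"].values())
            for g in params["groups"].values():
                g["n"] = max(1, round(g["n"] * n / total))
        else:
            params["n"] = int(n)
    return FixturePreset(name=name, n=n, true_params=params, seed=seed)


def _bool_series(values: np.ndarray) -> pd.Series:
    return pd.Series([bool(v) for v in values], dtype="object")


# ---------------------------------------------------------------------------
# categorical-outcome designs
# ---------------------------------------------------------------------------


def simulate_categorical_outcome_cohort(preset: FixturePreset) -> Cohort:
    """Subgroup labels at stated sizes with Bernoulli boolean outcomes."""
    rng = np.random.default_rng(preset.seed)
    p = preset.true_params
    if preset.name == "ppi_prescription":
        labels, outcomes = [], []
        for name in sorted(p["subgroups"]):
            sub = p["subgroups"][name]
            labels.extend([name] * sub["n"])
            outcomes.extend(rng.random(sub["n"]) < sub["p"])
        schema = [
            VariableSpec("subgroup", "categorical", "group", categories=tuple(sorted(p["subgroups"]))),
            VariableSpec("ppi", "boolean", "outcome"),
        ]
        return Cohort.from_columns(
            schema, {"subgroup": labels, "ppi": [bool(o) for o in outcomes]}
        )
    if preset.name == "imaging_aki":
        cols: dict[str, list] = {"mri": [], "aki": []}
        conf_names = sorted(p["confounders"])
        for nm in conf_names:
            cols[nm] = []
        for grp in ("mri", "ct"):
            g = p["groups"][grp]
            size = g["n"]
            cols["mri"].extend([grp == "mri"] * size)
            lp = np.full(size, g["base_logit"])
            for nm in conf_names:
                spec = p["confounders"][nm]
                flags = rng.random(size) < spec[grp]
                cols[nm].extend(bool(f) for f in flags)
                lp += spec["log_or"] * flags
            cols["aki"].extend(bool(v) for v in rng.random(size) < 1 / (1 + np.exp(-lp)))
        # quasi-identifying demographics first: privacy censoring blanks
        # earlier (tied-cardinality) columns first, so identifiers are
        # suppressed before the analytic exposure and outcome
        schema = [
            *[VariableSpec(nm, "boolean", "covariate") for nm in conf_names],
            VariableSpec("mri", "boolean", "group"),
            VariableSpec("aki", "boolean", "outcome"),
        ]
        return Cohort.from_columns(schema, {v.name: cols[v.name] for v in schema})
    raise ParameterError(
        f"preset {preset.name!r} is not a categorical-outcome design"
    )


# ---------------------------------------------------------------------------
# survival designs
# ---------------------------------------------------------------------------


def simulate_survival_cohort(preset: FixturePreset) -> Cohort:
    """Weibull event times under a linear log-hazard, administratively censored.

    ``S(t | x) = exp(−(t/scale)^shape · e^{xβ})``; records with latent times
    beyond the horizon are censored there.
    """
    if preset.name not in ("pci_stemi", "bun_adhf"):
        raise ParameterError(f"preset {preset.name!r} is not a survival design")
    rng = np.random.default_rng(preset.seed)
    p = preset.true_params
    n = int(p["n"])
    shape, scale, horizon = p["weibull_shape"], p["weibull_scale"], p["horizon"]
    if horizon < 0:
        raise ParameterError("horizon must be non-negative")

    lp = np.zeros(n)
    cols: dict[str, pd.Series] = {}
    schema: list[VariableSpec] = []

    if "category_var" in p:
        levels = list(p["category_levels"])
        probs = np.array([p["category_levels"][lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        draw = rng.choice(len(levels), size=n, p=probs)
        labels = [levels[i] for i in draw]
        for lv, beta in p["category_log_hazards"].items():
            lp += beta * (np.array(labels) == lv)
        schema.append(
            VariableSpec(p["category_var"], "categorical", "covariate", categories=tuple(levels))
        )
        cols[p["category_var"]] = pd.Series(labels, dtype="object")

    for nm in sorted(p.get("prevalence", {})):
        flags = rng.random(n) < p["prevalence"][nm]
        lp += p["log_hazards"].get(nm, 0.0) * flags
        schema.append(VariableSpec(nm, "boolean", "covariate"))
        cols[nm] = _bool_series(flags)

    latent = scale * (rng.exponential(1.0, n) / np.exp(lp)) ** (1.0 / shape)
    event = latent <= horizon
    time = np.minimum(latent, horizon)
    schema.append(VariableSpec("time_to_event", "continuous", "event_time", units="days"))
    schema.append(VariableSpec("event", "boolean", "event_indicator"))
    cols["time_to_event"] = pd.Series(time, dtype="object")
    cols["event"] = _bool_series(event)
    return Cohort.from_columns(schema, cols)


# ---------------------------------------------------------------------------
# logistic-interaction design
# ---------------------------------------------------------------------------


def simulate_binary_risk_cohort(preset: FixturePreset) -> Cohort:
    """Drug indicator × continuous albumin interaction on a binary outcome."""
    if preset.name != "insulin_hypoglycemia":
        raise ParameterError(f"preset {preset.name!r} is not a binary-risk design")
    rng = np.random.default_rng(preset.seed)
    p = preset.true_params
    n = int(p["n"])
    drug = rng.random(n) < p["p_drug"]
    albumin = np.clip(
        rng.normal(p["albumin_mean"], p["albumin_sd"], n), *p["albumin_range"]
    )
    dose = np.clip(rng.normal(p["dose_mean"], p["dose_sd"], n), 0.05, None)
    c = p["coef"]
    alb_c = albumin - p["albumin_mean"]
    lp = (
        c["intercept"]
        + c["drug"] * drug
        + c["albumin"] * alb_c
        + c["interaction"] * drug * alb_c
        + c.get("dose", 0.0) * (dose - p["dose_mean"])
    )
    outcome = rng.random(n) < 1 / (1 + np.exp(-lp))
    schema = [
        VariableSpec("detemir", "boolean", "group"),
        VariableSpec("albumin", "continuous", "covariate", units="g/dL"),
        VariableSpec("dose_per_kg", "continuous", "covariate", units="IU/kg"),
        VariableSpec("hypoglycemia", "boolean", "outcome"),
    ]
    return Cohort.from_columns(
        schema,
        {
            "detemir": _bool_series(drug),
            "albumin": pd.Series(albumin, dtype="object"),
            "dose_per_kg": pd.Series(dose, dtype="object"),
            "hypoglycemia": _bool_series(outcome),
        },
    )


def simulate(preset: FixturePreset) -> Cohort:
    """Dispatch a preset to its simulator."""
    if preset.name in ("ppi_prescription", "imaging_aki"):
        return simulate_categorical_outcome_cohort(preset)
    if preset.name in ("pci_stemi", "bun_adhf"):
        return simulate_survival_cohort(preset)
    return simulate_binary_risk_cohort(preset)


# ---------------------------------------------------------------------------
# deterministic small-subgroup fixture
# ---------------------------------------------------------------------------


def small_subgroup_cohort() -> Cohort:
    """Fixed cohort with one subgroup whose rarest cells sit below k=5.

    Cell counts are deterministic (no randomness), so privacy censoring at
    k=5 suppresses the sub-5 cells — shrinking the small subgroup — while
    k=2 leaves everything intact. Used to demonstrate that censoring widens
    the replicate range of the subgroup's outcome proportion.
    """
    cells = [
        # (subgroup, outcome, flag, count)
        ("big", True, "f0", 150),
        ("big", False, "f0", 100),
        ("big", True, "f1", 80),
        ("big", False, "f1", 70),
        ("small", True, "f0", 5),
        ("small", False, "f0", 5),
        ("small", True, "f1", 4),
        ("small", False, "f1", 4),
    ]
    sub, out, flag = [], [], []
    for s, o, f, cnt in cells:
        sub.extend([s] * cnt)
        out.extend([o] * cnt)
        flag.extend([f] * cnt)
    schema = [
        VariableSpec("subgroup", "categorical", "group", categories=("big", "small")),
        VariableSpec("ppi", "boolean", "outcome"),
        VariableSpec("flag", "categorical", "covariate", categories=("f0", "f1", "f2")),
    ]
    return Cohort.from_columns(schema, {"subgroup": sub, "ppi": out, "flag": flag})
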