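"""Distribution-free multivariate synthesis of cohort replicates.

The generative model is a stratified Gaussian copula over empirical
marginals. Every joint level of the categorical and boolean variables —
with missing counted as a level of its own, so that records missing a value
form their own subpopulation — defines a stratum. Within a stratum the
continuous variables are summarized by their sorted observed values (an
empirical quantile table), a per-variable missing fraction, and a
rank-based correlation matrix estimated on the normal-scores scale. No
parametric form is assumed for any marginal.

Sampling regenerates each stratum at its real count (``count_mode="exact"``,
so every purely categorical statistic of a replicate matches the source
cohort exactly) or at multinomially drawn counts (``"multinomial"``).
Continuous values are drawn by sampling a multivariate normal with the
stratum's correlation and pushing each coordinate through the stratum's
empirical quantile function, linearly interpolated between order statistics
and clamped to the observed range so no synthetic value escapes the real
support. Strata too small for a stable correlation estimate fall back to
independent resampling of their marginals with a small uniform jitter,
which also avoids verbatim value copying.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .censoring import CensoringReport
from .core import MISSING_LEVEL, Cohort, VariableSpec
from .errors import ParameterError, SchemaError

COUNT_MODES = ("exact", "multinomial")


@dataclass
class StratumModel:
    """Statistical summary of one categorical cross-classification cell."""

    cell_key: tuple  # one entry per categorical/boolean variable; MISSING_LEVEL allowed
    count: int
    marginals: Mapping[str, np.ndarray]  # sorted non-missing values per continuous var
    missing_frac: Mapping[str, float]
    rank_correlation: np.ndarray | None  # None ⇒ variables sampled independently

    @property
    def independent(self) -> bool:
        return self.rank_correlation is None


@dataclass
class SynthesisModel:
    """Everything needed to draw synthetic replicates of a cohort."""

    schema: list[VariableSpec]
    strata: list[StratumModel]
    n_total: int
    count_mode: str = "exact"
    small_cell_min: int = 10

    def __post_init__(self) -> None:
        if self.count_mode not in COUNT_MODES:
            raise ParameterError(f"count_mode must be one of {COUNT_MODES}")
        if sum(s.count for s in self.strata) != self.n_total:
            raise ParameterError("stratum counts do not sum to n_total")


def nearest_psd_correlation(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to a positive semidefinite correlation.

    Eigenvalues below ``floor`` are clipped and the diagonal renormalized to
    one. Pairwise-complete estimation can otherwise break PSD.
    """
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w.min() >= 0:
        return m
    w = np.clip(w, floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Van der Waerden-style scores: Φ⁻¹ of mid-ranks scaled to (0, 1)."""
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.5) / len(x))


def _pairwise_normal_score_corr(cols: list[np.ndarray]) -> np.ndarray:
    p = len(cols)
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            mask = ~np.isnan(cols[i]) & ~np.isnan(cols[j])
            m = int(mask.sum())
            if m < 3:
                rho = 0.0
            else:
                zi = _normal_scores(cols[i][mask])
                zj = _normal_scores(cols[j][mask])
                with np.errstate(invalid="ignore"):
                    rho = float(np.corrcoef(zi, zj)[0, 1])
                if not np.isfinite(rho):  # a constant column
                    rho = 0.0
            corr[i, j] = corr[j, i] = np.clip(rho, -1.0, 1.0)
    return nearest_psd_correlation(corr)


def fit_synthesis_model(
    cohort: Cohort, small_cell_min: int = 10, count_mode: str = "exact"
) -> SynthesisModel:
    """Extract the stratified copula summary from a (censored) cohort.

    One :class:`StratumModel` per observed categorical cell. Cells with at
    least ``small_cell_min`` records get a normal-scores rank-correlation
    matrix (pairwise-complete, PSD-repaired); smaller cells carry marginals
    only and are flagged independent.
    """
    if cohort.n == 0:
        raise ParameterError("cannot fit a synthesis model to an empty cohort")
    if small_cell_min < 1:
        raise ParameterError("small_cell_min must be positive")
    catnames = cohort.names(["categorical", "boolean"])
    contnames = cohort.names(["continuous"])
    df = cohort.data

    if catnames:
        keycols = []
        for nm in catnames:
            keycols.append([MISSING_LEVEL if pd.isna(v) else v for v in df[nm]])
        keys = list(zip(*keycols))
    else:
        keys = [()] * cohort.n
    groups: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)

    strata = []
    for key in sorted(groups, key=lambda t: tuple(map(str, t))):
        rows = groups[key]
        count = len(rows)
        marginals: dict[str, np.ndarray] = {}
        missing_frac: dict[str, float] = {}
        cols = []
        for nm in contnames:
            x = df[nm].to_numpy()[rows]
            obs = np.sort(x[~np.isnan(x)])
            marginals[nm] = obs
            missing_frac[nm] = 1.0 - len(obs) / count
            cols.append(x)
        if contnames and count >= small_cell_min:
            corr = _pairwise_normal_score_corr(cols)
        else:
            corr = None
        strata.append(StratumModel(key, count, marginals, missing_frac, corr))
    return SynthesisModel(
        schema=list(cohort.schema),
        strata=strata,
        n_total=cohort.n,
        count_mode=count_mode,
        small_cell_min=small_cell_min,
    )


def _empirical_quantile(u: np.ndarray, sorted_vals: np.ndarray) -> np.ndarray:
    """Invert the empirical CDF by interpolation between order statistics."""
    m = len(sorted_vals)
    if m == 1:
        return np.full(len(u), sorted_vals[0])
    p = (np.arange(1, m + 1) - 0.5) / m
    return np.interp(u, p, sorted_vals)  # np.interp clamps at the endpoints


def sample_synthetic(model: SynthesisModel, seed: int) -> Cohort:
    """Draw one synthetic cohort from a fitted model.

    Deterministic in ``(model, seed)``: the same pair reproduces the cohort
    bit-identically; different seeds give different continuous draws.
    """
    rng = np.random.default_rng(seed)
    catnames = [v.name for v in model.schema if v.kind in ("categorical", "boolean")]
    contnames = [v.name for v in model.schema if v.kind == "continuous"]
    kinds = {v.name: v.kind for v in model.schema}

    if model.count_mode == "exact":
        sizes = [s.count for s in model.strata]
    else:
        probs = np.array([s.count for s in model.strata], dtype=float) / model.n_total
        sizes = rng.multinomial(model.n_total, probs).tolist()

    blocks: dict[str, list] = {v.name: [] for v in model.schema}
    for stratum, size in zip(model.strata, sizes):
        if size == 0:
            continue
        for nm, val in zip(catnames, stratum.cell_key):
            if val == MISSING_LEVEL:
                fill = pd.NA if kinds[nm] == "boolean" else np.nan
            else:
                fill = val
            blocks[nm].extend([fill] * size)

        if not contnames:
            continue
        if stratum.independent:
            for nm in contnames:
                vals = stratum.marginals[nm]
                m = len(vals)
                if m == 0:
                    x = np.full(size, np.nan)
                else:
                    x = vals[rng.integers(0, m, size)].astype(float)
                    if m > 1:
                        gap = (vals[-1] - vals[0]) / (m - 1)
                        x = x + rng.uniform(-gap / 2.0, gap / 2.0, size)
                        x = np.clip(x, vals[0], vals[-1])
                    mf = stratum.missing_frac[nm]
                    if mf > 0:
                        x[rng.random(size) < mf] = np.nan
                blocks[nm].extend(x.tolist())
        else:
            corr = stratum.rank_correlation
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(contnames)))
            z = rng.standard_normal((size, len(contnames))) @ chol.T
            u = stats.norm.cdf(z)
            for j, nm in enumerate(contnames):
                vals = stratum.marginals[nm]
                if len(vals) == 0:
                    x = np.full(size, np.nan)
                else:
                    x = _empirical_quantile(u[:, j], vals)
                    mf = stratum.missing_frac[nm]
                    if mf > 0:
                        x[rng.random(size) < mf] = np.nan
                blocks[nm].extend(x.tolist())

    df = pd.DataFrame(
        {nm: pd.Series(col, dtype="object") for nm, col in blocks.items()},
        columns=[v.name for v in model.schema],
    )
    return Cohort(model.schema, df)


# ---------------------------------------------------------------------------
# QC report: real vs synthetic marginals and pairwise associations
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Real-vs-synthetic fidelity report produced alongside every synthesis."""

    censoring: CensoringReport
    per_variable: Mapping[str, Mapping]
    correlation_variables: list[str]
    correlation_delta: np.ndarray
    max_abs_correlation_delta: float

    def to_dict(self) -> dict:
        return {
            "censoring": self.censoring.to_dict(),
            "per_variable": {k: dict(v) for k, v in self.per_variable.items()},
            "correlation_variables": list(self.correlation_variables),
            "correlation_delta": np.round(self.correlation_delta, 10).tolist(),
            "max_abs_correlation_delta": self.max_abs_correlation_delta,
        }


def _summary_continuous(x: np.ndarray) -> dict:
    obs = x[~np.isnan(x)]
    if len(obs) == 0:
        return {"n": 0, "missing_frac": 1.0}
    q1, med, q3 = np.percentile(obs, [25, 50, 75])
    return {
        "n": int(len(obs)),
        "missing_frac": float(1 - len(obs) / len(x)),
        "mean": float(obs.mean()),
        "sd": float(obs.std(ddof=1)) if len(obs) > 1 else 0.0,
        "min": float(obs.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(obs.max()),
    }


def _summary_categorical(col: pd.Series, n: int) -> dict:
    counts: dict[str, int] = {}
    miss = 0
    for v in col:
        if pd.isna(v):
            miss += 1
        else:
            label = "true" if v is True else ("false" if v is False else str(v))
            counts[label] = counts.get(label, 0) + 1
    freqs = {k: counts[k] / n for k in sorted(counts)}
    return {"missing_frac": miss / n if n else 0.0, "frequencies": freqs}


def _cramers_v(a: pd.Series, b: pd.Series) -> float:
    mask = ~(a.isna() | b.isna())
    if mask.sum() < 2:
        return 0.0
    tab = pd.crosstab(a[mask].astype(str), b[mask].astype(str))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab.to_numpy(), correction=False)[0]
    n = tab.to_numpy().sum()
    denom = n * (min(tab.shape) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else 0.0


def _rank_point_biserial(b: pd.Series, x: pd.Series) -> float:
    mask = ~(b.isna() | x.isna())
    if mask.sum() < 3:
        return 0.0
    bi = b[mask].astype(bool).to_numpy().astype(float)
    ranks = stats.rankdata(x[mask].to_numpy(dtype=float))
    if bi.std() == 0 or ranks.std() == 0:
        return 0.0
    return float(np.corrcoef(bi, ranks)[0, 1])


def _rank_correlation_ratio(c: pd.Series, x: pd.Series) -> float:
    # η on ranks for multi-level categorical vs continuous
    mask = ~(c.isna() | x.isna())
    if mask.sum() < 3:
        return 0.0
    ranks = stats.rankdata(x[mask].to_numpy(dtype=float))
    labels = c[mask].astype(str).to_numpy()
    grand = ranks.mean()
    ss_total = ((ranks - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = sum(
        len(g) * (g.mean() - grand) ** 2
        for g in (ranks[labels == lv] for lv in np.unique(labels))
    )
    return float(np.sqrt(ss_between / ss_total))


def mixed_correlation_matrix(cohort: Cohort) -> tuple[list[str], np.ndarray]:
    """All pairwise associations, pairwise-complete, on a common [−1, 1]-ish scale.

    Spearman for continuous–continuous, point-biserial on ranks for
    boolean–continuous, Cramér's V for categorical–categorical (booleans
    treated as two-level categoricals), correlation ratio on ranks for
    multi-level categorical vs continuous.
    """
    names = [v.name for v in cohort.schema]
    kinds = {v.name: v.kind for v in cohort.schema}
    p = len(names)
    mat = np.eye(p)
    df = cohort.data
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            ka, kb = kinds[a], kinds[b]
            if ka == "continuous" and kb == "continuous":
                mask = ~(df[a].isna() | df[b].isna())
                if mask.sum() < 3:
                    rho = 0.0
                else:
                    rho = stats.spearmanr(
                        df.loc[mask, a].astype(float), df.loc[mask, b].astype(float)
                    ).statistic
                    rho = float(rho) if np.isfinite(rho) else 0.0
            elif {ka, kb} == {"boolean", "continuous"}:
                bo, co = (a, b) if ka == "boolean" else (b, a)
                rho = _rank_point_biserial(df[bo], df[co])
            elif "continuous" not in (ka, kb):
                rho = _cramers_v(df[a], df[b])
            else:
                ca, co = (a, b) if kb == "continuous" else (b, a)
                rho = _rank_correlation_ratio(df[ca], df[co])
            mat[i, j] = mat[j, i] = rho
    return names, mat


def qc_report(real: Cohort, synthetic: Cohort, censoring: CensoringReport) -> QCReport:
    """Compare a synthetic cohort against its source, variable by variable."""
    if [v.to_dict() for v in real.schema] != [v.to_dict() for v in synthetic.schema]:
        raise SchemaError("real and synthetic cohorts have different schemas")
    per_var: dict[str, dict] = {}
    for var in real.schema:
        if var.kind == "continuous":
            per_var[var.name] = {
                "kind": var.kind,
                "real": _summary_continuous(real.data[var.name].to_numpy(dtype=float)),
                "synthetic": _summary_continuous(
                    synthetic.data[var.name].to_numpy(dtype=float)
                ),
            }
        else:
            per_var[var.name] = {
                "kind": var.kind,
                "real": _summary_categorical(real.data[var.name], real.n),
                "synthetic": _summary_categorical(synthetic.data[var.name], synthetic.n),
            }
    names, real_corr = mixed_correlation_matrix(real)
    _, syn_corr = mixed_correlation_matrix(synthetic)
    delta = real_corr - syn_corr
    np.fill_diagonal(delta, 0.0)
    off = np.abs(delta)
    return QCReport(
        censoring=censoring,
        per_variable=per_var,
        correlation_variables=names,
        correlation_delta=delta,
        max_abs_correlation_delta=float(off.max()) if len(names) > 1 else 0.0,
    )
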