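"""Replicate-based validation of synthetic-data analyses.

The protocol: censor the real cohort, fit the synthesis model once, draw K
synthetic replicates, run every declared estimand on the real cohort and on
each replicate, and quantify three things per estimand —

* **bias**: mean replicate point estimate minus the real point estimate,
  on the estimand's natural scale (log scale for odds and hazard ratios);
* **stability**: the min-to-max range of the replicate-minus-real
  differences;
* **containment**: the fraction of replicate points falling inside the
  real-data 95% confidence interval (and, for survival curves, the
  fraction of time-grid points where the mean replicate curve lies inside
  the real Greenwood band).

Replicate seeds derive deterministically from the master seed, so a rerun
with the same seed reproduces every replicate bit-identically. A replicate
on which an estimator fails (e.g. non-convergence on a small draw) is
recorded and excluded from the summaries; it never aborts the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .censoring import censor_unique_cells
from .core import Cohort
from .errors import EstimationError, ParameterError
from .estimators import EstimandSpec, EstimateResult, run_estimand
from .synthesis import SynthesisModel, fit_synthesis_model, sample_synthetic

#: signature of a replicate generator; the default is :func:`sample_synthetic`
Generator = Callable[[SynthesisModel, int], Cohort]


@dataclass
class ValidationReport:
    """Bias / stability / containment summary for one estimand."""

    estimand_id: str
    real: EstimateResult
    replicates: list[EstimateResult]
    bias: float
    range_low: float
    range_high: float
    containment: float
    curve_containment: float | None
    K: int
    seed: int
    failures: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimand_id": self.estimand_id,
            "real": self.real.to_dict(),
            "replicates": [r.to_dict() for r in self.replicates],
            "bias": self.bias,
            "range_low": self.range_low,
            "range_high": self.range_high,
            "containment": self.containment,
            "curve_containment": self.curve_containment,
            "K": self.K,
            "seed": self.seed,
            "failures": self.failures,
        }


def replicate_seeds(seed: int, K: int) -> tuple[int, list[int]]:
    """Deterministic (matching seed, K replicate seeds) schedule.

    The matching seed is shared by the real analysis and every replicate so
    that identical cohorts yield identical matched analyses; replicate
    synthesis seeds are distinct. All values stay below 2**31.
    """
    state = np.random.SeedSequence(seed).generate_state(K + 1, dtype=np.uint32)
    vals = (state & 0x7FFFFFFF).astype(int)
    return int(vals[0]), [int(v) for v in vals[1:]]


def _eval_step(times: np.ndarray, values: np.ndarray, grid: np.ndarray, before: float = 1.0) -> np.ndarray:
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, None)], before)
    return out.astype(float)


def compare_curves(real: EstimateResult, replicates: Sequence[EstimateResult]) -> dict:
    """Pointwise mean and envelope of replicate survival curves vs the real band.

    Step functions are re-evaluated on the union time grid. Returns the
    grid, the mean replicate curve, its min/max envelope, and the fraction
    of grid points where the mean curve lies inside the real 95% band.
    """
    if real.curve is None or any(r.curve is None for r in replicates) or not replicates:
        raise ParameterError("compare_curves requires curves on all results")
    real_t = np.array([p[0] for p in real.curve])
    grid = set(real_t.tolist())
    for r in replicates:
        grid.update(p[0] for p in r.curve)
    grid = np.array(sorted(grid))

    rep_vals = []
    for r in replicates:
        t = np.array([p[0] for p in r.curve])
        s = np.array([p[1] for p in r.curve])
        rep_vals.append(_eval_step(t, s, grid))
    rep_vals = np.vstack(rep_vals)
    mean_curve = rep_vals.mean(axis=0)
    env_low = rep_vals.min(axis=0)
    env_high = rep_vals.max(axis=0)

    band_low = _eval_step(real_t, np.array([p[2] for p in real.curve]), grid)
    band_high = _eval_step(real_t, np.array([p[3] for p in real.curve]), grid)
    eps = 1e-12
    inside = (mean_curve >= band_low - eps) & (mean_curve <= band_high + eps)
    return {
        "grid": grid.tolist(),
        "mean_curve": mean_curve.tolist(),
        "envelope_low": env_low.tolist(),
        "envelope_high": env_high.tolist(),
        "containment": float(inside.mean()),
    }


def run_validation(
    real: Cohort,
    specs: Sequence[EstimandSpec],
    k_privacy: int = 5,
    K: int = 5,
    seed: int = 0,
    count_mode: str = "exact",
    small_cell_min: int = 10,
    generator: Generator | None = None,
) -> list[ValidationReport]:
    """Run the full censor → synthesize → re-analyze → compare protocol.

    ``generator`` substitutes the replicate source (a callable of
    ``(model, replicate_seed) -> Cohort``); the default draws from the
    fitted synthesis model. K=5 matches interactive use; bias studies use
    K=1000.
    """
    if K < 1:
        raise ParameterError("K must be ≥ 1")
    for spec in specs:
        spec.validate_against(real.schema)

    censored, _ = censor_unique_cells(real, k_privacy)
    model = fit_synthesis_model(censored, small_cell_min=small_cell_min, count_mode=count_mode)
    gen = generator if generator is not None else sample_synthetic
    match_seed, rep_seeds = replicate_seeds(seed, K)

    real_results: dict[str, EstimateResult] = {}
    spec_ids: dict[str, list[str]] = {}
    for spec in specs:
        results = run_estimand(real, spec, seed=match_seed)
        spec_ids[spec.id] = [r.estimand_id for r in results]
        for r in results:
            real_results[r.estimand_id] = r

    rep_results: dict[str, list[EstimateResult]] = {eid: [] for eid in real_results}
    failures: dict[str, list[dict]] = {eid: [] for eid in real_results}
    for r_idx in range(K):
        replicate = gen(model, rep_seeds[r_idx])
        for spec in specs:
            try:
                results = run_estimand(replicate, spec, seed=match_seed)
            except (EstimationError, ParameterError) as exc:
                for eid in spec_ids[spec.id]:
                    failures[eid].append({"replicate": r_idx, "error": str(exc)})
                continue
            got = {r.estimand_id: r for r in results}
            for eid in spec_ids[spec.id]:
                if eid in got:
                    rep_results[eid].append(got[eid])
                else:
                    failures[eid].append(
                        {"replicate": r_idx, "error": f"coefficient {eid!r} absent"}
                    )

    reports = []
    for eid, real_res in real_results.items():
        reps = rep_results[eid]
        if reps:
            diffs = np.array([r.point for r in reps]) - real_res.point
            bias = float(diffs.mean())
            range_low = float(diffs.min())
            range_high = float(diffs.max())
            inside = [
                real_res.ci_low <= r.point <= real_res.ci_high for r in reps
            ]
            containment = float(np.mean(inside))
        else:
            bias = range_low = range_high = float("nan")
            containment = float("nan")
        curve_containment = None
        if real_res.curve is not None and reps and all(r.curve is not None for r in reps):
            curve_containment = compare_curves(real_res, reps)["containment"]
        reports.append(
            ValidationReport(
                estimand_id=eid,
                real=real_res,
                replicates=reps,
                bias=bias,
                range_low=range_low,
                range_high=range_high,
                containment=containment,
                curve_containment=curve_containment,
                K=K,
                seed=seed,
                failures=failures[eid],
            )
        )
    return reports


def summarize_validation(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    """One row per estimand: real estimate, bias, range, containment, failures."""
    if not reports:
        raise ParameterError("no reports to summarize")
    rows = []
    for rep in reports:
        rows.append(
            {
                "estimand_id": rep.estimand_id,
                "scale": rep.real.scale,
                "real_point": rep.real.point,
                "real_ci_low": rep.real.ci_low,
                "real_ci_high": rep.real.ci_high,
                "bias": rep.bias,
                "range_low": rep.range_low,
                "range_high": rep.range_high,
                "containment": rep.containment,
                "curve_containment": rep.curve_containment,
                "K": rep.K,
                "n_failed": len(rep.failures),
            }
        )
    return pd.DataFrame(rows)


def summary_to_json(summary: pd.DataFrame) -> str:
    return json.dumps(summary.to_dict(orient="records"), indent=2, allow_nan=True)


def summary_from_json(text: str) -> pd.DataFrame:
    return pd.DataFrame(json.loads(text))
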