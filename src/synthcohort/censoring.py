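"""Small-cell suppression of identifying categorical combinations.

Before any statistics are extracted for synthesis, the joint
cross-classification of every categorical and boolean variable (a missing
value counts as its own level) is scanned for cells containing fewer than
``k`` patients. Such a combination could identify individuals, so the
offending values are censored — replaced by missing — until every cell that
still carries a non-missing categorical pattern holds at least ``k``
records. Continuous values are never modified here; their re-identification
defense is the resampling performed by the synthesis engine.

The algorithm is deterministic: while an offending cell exists, blank the
variable with the largest number of schema levels among the cell's
non-missing variables (ties broken by schema order) for all the cell's
records, then rescan. Blanking high-cardinality variables merges cells
fastest, minimizing information loss.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MISSING_LEVEL, Cohort
from .errors import ParameterError


@dataclass(frozen=True)
class CensoringReport:
    """Audit record of one censoring pass.

    ``per_variable_rate`` maps every schema variable to the fraction of
    records whose value was blanked (continuous variables are always 0).
    """

    k_threshold: int
    per_variable_rate: Mapping[str, float]
    cells_censored: int
    records_touched: int

    def to_dict(self) -> dict:
        return {
            "k_threshold": self.k_threshold,
            "per_variable_rate": dict(self.per_variable_rate),
            "cells_censored": self.cells_censored,
            "records_touched": self.records_touched,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CensoringReport":
        return cls(
            k_threshold=int(d["k_threshold"]),
            per_variable_rate={k: float(v) for k, v in d["per_variable_rate"].items()},
            cells_censored=int(d["cells_censored"]),
            records_touched=int(d["records_touched"]),
        )

    @classmethod
    def empty(cls, cohort: Cohort, k: int = 2) -> "CensoringReport":
        return cls(k, {v.name: 0.0 for v in cohort.schema}, 0, 0)


def _cell_keys(df: pd.DataFrame, names: list[str]) -> list[tuple]:
    cols = []
    for name in names:
        col = df[name]
        filled = [MISSING_LEVEL if pd.isna(v) else v for v in col]
        cols.append(filled)
    return list(zip(*cols)) if names else []


def censor_unique_cells(cohort: Cohort, k: int = 5) -> tuple[Cohort, CensoringReport]:
    """Suppress categorical combinations held by fewer than ``k`` patients.

    Returns the censored cohort and a :class:`CensoringReport`. Idempotent:
    censoring an already-censored cohort with the same ``k`` is a no-op.
    """
    if k < 2:
        raise ParameterError(f"k must be at least 2, got {k}")
    df = cohort.data.copy()
    catvars = [v for v in cohort.schema if v.kind in ("categorical", "boolean")]
    names = [v.name for v in catvars]
    cardinality = {
        v.name: (len(v.categories) if v.kind == "categorical" else 2) for v in catvars
    }
    order = {v.name: i for i, v in enumerate(cohort.schema)}
    n = len(df)
    replaced = {v.name: 0 for v in cohort.schema}
    touched: set[int] = set()
    cells_censored = 0

    while names and n:
        cells: dict[tuple, list[int]] = defaultdict(list)
        for idx, key in enumerate(_cell_keys(df, names)):
            cells[key].append(idx)
        offending = []
        for key in sorted(cells, key=lambda t: tuple(map(str, t))):
            rows = cells[key]
            if len(rows) >= k:
                continue
            present = [nm for nm, val in zip(names, key) if val != MISSING_LEVEL]
            if present:
                offending.append((key, rows, present))
        if not offending:
            break
        for key, rows, present in offending:
            # blank the widest variable; ties fall back to schema order
            target = max(present, key=lambda nm: (cardinality[nm], -order[nm]))
            col = df[target]
            missing = pd.NA if cohort.variable(target).kind == "boolean" else np.nan
            df.loc[rows, target] = missing
            replaced[target] += len(rows)
            touched.update(rows)
            cells_censored += 1

    report = CensoringReport(
        k_threshold=k,
        per_variable_rate={nm: (cnt / n if n else 0.0) for nm, cnt in replaced.items()},
        cells_censored=cells_censored,
        records_touched=len(touched),
    )
    return Cohort(cohort.schema, df), report
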