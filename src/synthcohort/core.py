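"""Typed cohort tables, variable schemas, and CSV/JSON I/O.

A cohort is a rectangular patient-by-variable table. Each variable is
declared in a schema (:class:`VariableSpec`) as categorical, boolean, or
continuous, with an analysis role. Values either conform to their declared
kind or are missing; missingness is explicit (empty CSV field, ``NaN`` /
``pd.NA`` in memory) and is preserved through round-trips. The data model
is identifier-free by construction: there is no patient-id column and no
datetime kind — times are continuous offsets relative to an index event.

Files are plain CSV (RFC 4180, UTF-8, "." decimal point, empty field =
missing, booleans as ``true``/``false``) plus a JSON schema: an array of
variable objects. Every downstream module consumes only these two forms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortParseError, SchemaError

KINDS = ("categorical", "boolean", "continuous")
ROLES = ("covariate", "outcome", "event_time", "event_indicator", "group", "stratum")

#: sentinel used internally when a missing level must act as its own category
MISSING_LEVEL = "∅missing"


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"categorical", "boolean", "continuous"}
    role : {"covariate", "outcome", "event_time", "event_indicator", "group", "stratum"}
        How the variable is used by estimators. ``event_time`` requires a
        continuous kind with non-negative values; ``event_indicator``
        requires boolean.
    categories : tuple of str, optional
        Ordered level labels; required (non-empty) iff kind is categorical.
        The first label is the reference level for model dummies.
    units : str, optional
        Free-text units, documentation only.
    """

    name: str
    kind: str
    role: str = "covariate"
    categories: tuple[str, ...] | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise SchemaError("variable name must be a non-empty string")
        if self.kind not in KINDS:
            raise SchemaError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.role not in ROLES:
            raise SchemaError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise SchemaError(
                    f"categorical variable {self.name!r} needs non-empty categories"
                )
            cats = tuple(str(c) for c in self.categories)
            if len(set(cats)) != len(cats):
                raise SchemaError(f"variable {self.name!r}: duplicate categories")
            object.__setattr__(self, "categories", cats)
        elif self.categories:
            raise SchemaError(
                f"variable {self.name!r}: categories only allowed for categorical kind"
            )
        if self.role == "event_time" and self.kind != "continuous":
            raise SchemaError(f"event_time variable {self.name!r} must be continuous")
        if self.role == "event_indicator" and self.kind != "boolean":
            raise SchemaError(f"event_indicator variable {self.name!r} must be boolean")

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind, "role": self.role}
        if self.categories is not None:
            d["categories"] = list(self.categories)
        if self.units is not None:
            d["units"] = self.units
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSpec":
        unknown = set(d) - {"name", "kind", "role", "categories", "units"}
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        cats = d.get("categories")
        return cls(
            name=d.get("name", ""),
            kind=d.get("kind", ""),
            role=d.get("role", "covariate"),
            categories=tuple(cats) if cats is not None else None,
            units=d.get("units"),
        )


def _check_unique_names(schema: Sequence[VariableSpec]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names in schema: {dup}")


def load_schema(path) -> list[VariableSpec]:
    """Read a JSON schema file (array of variable objects)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise SchemaError("schema file must contain a JSON array of variables")
    schema = [VariableSpec.from_dict(d) for d in raw]
    _check_unique_names(schema)
    return schema


def save_schema(schema: Sequence[VariableSpec], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([v.to_dict() for v in schema], fh, indent=2)
        fh.write("\n")


class Cohort:
    """A validated patient-by-variable table bound to its schema.

    The backing :class:`pandas.DataFrame` uses object dtype for categorical
    columns (``str`` values, ``NaN`` missing), nullable ``boolean`` dtype for
    boolean columns, and ``float64`` for continuous columns. Construction
    validates every cell; invalid cohorts cannot exist silently.
    """

    def __init__(self, schema: Sequence[VariableSpec], data: pd.DataFrame):
        schema = list(schema)
        _check_unique_names(schema)
        if list(data.columns) != [v.name for v in schema]:
            raise SchemaError(
                f"data columns {list(data.columns)} do not match schema names "
                f"{[v.name for v in schema]}"
            )
        self.schema = schema
        self.data = self._coerce_and_validate(schema, data)

    @staticmethod
    def _coerce_and_validate(schema: Sequence[VariableSpec], data: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for var in schema:
            col = data[var.name]
            if var.kind == "continuous":
                try:
                    vals = pd.to_numeric(col, errors="raise").astype("float64")
                except (ValueError, TypeError) as exc:
                    raise CohortParseError(
                        f"column {var.name!r}: non-numeric value ({exc})"
                    ) from None
                finite = np.isfinite(vals.to_numpy()) | np.isnan(vals.to_numpy())
                if not finite.all():
                    row = int(np.flatnonzero(~finite)[0])
                    raise CohortParseError(
                        f"column {var.name!r}, row {row}: non-finite value"
                    )
                if var.role == "event_time":
                    bad = vals.to_numpy() < 0
                    if np.nansum(bad) > 0:
                        row = int(np.flatnonzero(bad)[0])
                        raise CohortParseError(
                            f"event_time column {var.name!r}, row {row}: negative value"
                        )
                out[var.name] = vals
            elif var.kind == "boolean":
                coerced = []
                for i, v in enumerate(col):
                    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
                        coerced.append(pd.NA)
                    elif isinstance(v, (bool, np.bool_)):
                        coerced.append(bool(v))
                    else:
                        raise CohortParseError(
                            f"column {var.name!r}, row {i}: value {v!r} is not boolean"
                        )
                out[var.name] = pd.array(coerced, dtype="boolean")
            else:  # categorical
                allowed = set(var.categories)
                coerced = []
                for i, v in enumerate(col):
                    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
                        coerced.append(np.nan)
                    elif isinstance(v, str) and v in allowed:
                        coerced.append(v)
                    else:
                        raise CohortParseError(
                            f"column {var.name!r}, row {i}: value {v!r} not in "
                            f"categories {list(var.categories)}"
                        )
                out[var.name] = pd.Series(coerced, dtype="object")
        df = pd.DataFrame(out, columns=[v.name for v in schema])
        df.index = pd.RangeIndex(len(df))
        return df

    # -- convenience -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def variable(self, name: str) -> VariableSpec:
        for v in self.schema:
            if v.name == name:
                return v
        raise SchemaError(f"no variable named {name!r} in schema")

    def names(self, kinds: Iterable[str] | None = None) -> list[str]:
        kinds = set(kinds) if kinds is not None else set(KINDS)
        return [v.name for v in self.schema if v.kind in kinds]

    def subset(self, mask) -> "Cohort":
        return Cohort(self.schema, self.data.loc[np.asarray(mask)].reset_index(drop=True))

    def equals(self, other: "Cohort") -> bool:
        if [v.to_dict() for v in self.schema] != [v.to_dict() for v in other.schema]:
            return False
        if self.n != other.n:
            return False
        for v in self.schema:
            a, b = self.data[v.name], other.data[v.name]
            ma, mb = a.isna().to_numpy(), b.isna().to_numpy()
            if not np.array_equal(ma, mb):
                return False
            if v.kind == "continuous":
                if not np.array_equal(a.to_numpy()[~ma], b.to_numpy()[~mb]):
                    return False
            else:
                if not (a[~ma].to_numpy() == b[~mb].to_numpy()).all():
                    return False
        return True

    @classmethod
    def from_columns(cls, schema: Sequence[VariableSpec], columns: Mapping[str, Sequence]) -> "Cohort":
        """Build a cohort from per-variable value sequences (schema order)."""
        df = pd.DataFrame({v.name: pd.Series(columns[v.name], dtype="object") for v in schema})
        return cls(schema, df)


def read_cohort(path, schema_path) -> Cohort:
    """Read a cohort CSV against its JSON schema.

    Empty CSV fields become missing values. The CSV header must match the
    schema names exactly (same names, same order).
    """
    schema = load_schema(schema_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    if list(df.columns) != [v.name for v in schema]:
        raise SchemaError(
            f"CSV header {list(df.columns)} does not match schema "
            f"{[v.name for v in schema]}"
        )
    out = {}
    for var in schema:
        raw = df[var.name].to_numpy(dtype=object)
        if var.kind == "continuous":
            vals = []
            for i, s in enumerate(raw):
                if s == "":
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(s))
                    except ValueError:
                        raise CohortParseError(
                            f"column {var.name!r}, row {i}: cannot parse {s!r} as number"
                        ) from None
            out[var.name] = pd.Series(vals, dtype="float64")
        elif var.kind == "boolean":
            vals = []
            for i, s in enumerate(raw):
                if s == "":
                    vals.append(pd.NA)
                elif s == "true":
                    vals.append(True)
                elif s == "false":
                    vals.append(False)
                else:
                    raise CohortParseError(
                        f"column {var.name!r}, row {i}: {s!r} is not 'true'/'false'"
                    )
            out[var.name] = pd.Series(vals, dtype="object")
        else:
            vals = [np.nan if s == "" else s for s in raw]
            out[var.name] = pd.Series(vals, dtype="object")
    return Cohort(schema, pd.DataFrame(out, columns=[v.name for v in schema]))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as RFC 4180 CSV; missing values become empty fields.

    ``read_cohort(write_cohort(c))`` reproduces ``c`` value-for-value:
    floats are serialized with ``repr`` so float64 round-trips exactly.
    """
    cols = {}
    for var in cohort.schema:
        col = cohort.data[var.name]
        if var.kind == "continuous":
            cols[var.name] = [
                "" if math.isnan(v) else repr(float(v)) for v in col.to_numpy()
            ]
        elif var.kind == "boolean":
            cols[var.name] = [
                "" if v is pd.NA else ("true" if v else "false") for v in col
            ]
        else:
            cols[var.name] = ["" if isinstance(v, float) else v for v in col]
    pd.DataFrame(cols, columns=[v.name for v in cohort.schema]).to_csv(
        path, index=False, lineterminator="\n"
    )
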