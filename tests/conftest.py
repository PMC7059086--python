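import numpy as np
import pandas as pd
import pytest

from synthcohort.core import Cohort, VariableSpec


@pytest.fixture
def sex_smoker_schema():
    return [
        VariableSpec("sex", "categorical", categories=("m", "f")),
        VariableSpec("smoker", "boolean"),
    ]


def make_cohort(schema, rows):
    """Rows given as list of tuples in schema order; None means missing."""
    cols = {v.name: [r[i] for r in rows] for i, v in enumerate(schema)}
    return Cohort.from_columns(schema, cols)


def random_cohort(rng: np.random.Generator, n_rows: int | None = None) -> Cohort:
    """A random valid cohort (mixed kinds, some missing values) for property tests."""
    n = int(rng.integers(0, 40)) if n_rows is None else n_rows
    schema = []
    cols = {}
    n_vars = int(rng.integers(1, 5))
    for i in range(n_vars):
        kind = ["categorical", "boolean", "continuous"][int(rng.integers(0, 3))]
        name = f"v{i}"
        if kind == "categorical":
            levels = tuple(f"l{j}" for j in range(int(rng.integers(2, 5))))
            schema.append(VariableSpec(name, kind, categories=levels))
            vals = [
                None if rng.random() < 0.15 else levels[int(rng.integers(0, len(levels)))]
                for _ in range(n)
            ]
        elif kind == "boolean":
            schema.append(VariableSpec(name, kind))
            vals = [None if rng.random() < 0.15 else bool(rng.integers(0, 2)) for _ in range(n)]
        else:
            schema.append(VariableSpec(name, kind))
            vals = [
                None if rng.random() < 0.15 else float(np.round(rng.normal(), 6))
                for _ in range(n)
            ]
        cols[name] = vals
    return Cohort.from_columns(schema, cols)
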