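"""Shared fixtures: tiny in-memory tables built programmatically."""

import numpy as np
import pandas as pd
import pytest

import oimtools as ot

CATEGORY = "Vegetable oil"


def make_occurrence(strata_values, category=CATEGORY, lod=0.035):
    """OccurrenceTable from {stratum: [values]}; censored where value < lod."""
    rows = []
    i = 0
    for s, vals in strata_values.items():
        for v in vals:
            rows.append(
                {
                    "sample_id": f"x{i:03d}",
                    "category": category,
                    "subcategory": s,
                    "value": float(v),
                    "lod": lod,
                    "censored": bool(v < lod),
                }
            )
            i += 1
    return ot.OccurrenceTable(pd.DataFrame(rows))


def make_consumers(body_weights, amounts, subcategories=("OO",), category=CATEGORY,
                   ages=None):
    """ConsumerTable from body weights (kg) and an (n x n_sub) amount array."""
    n = len(body_weights)
    amounts = np.atleast_2d(np.asarray(amounts, dtype=float))
    if amounts.shape[0] != n:
        amounts = amounts.reshape(n, -1)
    ids = [f"C{i:03d}" for i in range(n)]
    subjects = pd.DataFrame(
        {
            "body_weight": np.asarray(body_weights, dtype=float),
            "age": ages if ages is not None else np.full(n, 40.0),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    intake = pd.DataFrame(
        amounts,
        index=subjects.index,
        columns=pd.MultiIndex.from_tuples(
            [(category, s) for s in subcategories], names=["category", "subcategory"]
        ),
    )
    return ot.ConsumerTable(subjects=subjects, intake=intake, survey_days=1)


@pytest.fixture
def occ_factory():
    return make_occurrence


@pytest.fixture
def consumer_factory():
    return make_consumers


@pytest.fixture
def three_strata_table():
    """Stratum means exactly {SO: 1, OO: 2, EVOO: 3} ug/g."""
    return make_occurrence(
        {"SO": [0.5, 1.5], "OO": [1.0, 3.0], "EVOO": [2.0, 4.0]}
    )


@pytest.fixture
def contrasted_table():
    """Two strata with well-separated means (0.2 vs 1.7 ug/g)."""
    rng = np.random.default_rng(42)
    return make_occurrence(
        {
            "low": 0.2 * rng.lognormal(0, 0.3, 30) / np.exp(0.045),
            "high": 1.7 * rng.lognormal(0, 0.3, 30) / np.exp(0.045),
        }
    )
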