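"""Shared fixtures: small deterministic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from fedcpm.synthetic_cohort import (
    CohortTable,
    generate_cohort,
    iid_config,
    inject_missingness,
)

SIGNAL_BETA = {"x00": 0.8, "x01": -0.7, "x14": 0.9}


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """Six IID hospitals, 900 records, 10% prevalence, three signal variables,
    no missingness.  Cheap enough for end-to-end runs."""
    cfg = iid_config(
        n_records=900, n_hospitals=6, seed=42, beta=SIGNAL_BETA,
        n_predictors=20, prevalence=0.10,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def missing_cohort() -> CohortTable:
    """Like ``small_cohort`` but with MAR missingness on two variables."""
    cfg = iid_config(
        n_records=900, n_hospitals=6, seed=43, beta=SIGNAL_BETA,
        n_predictors=20, prevalence=0.10,
    )
    from dataclasses import replace

    names = cfg.predictor_names
    rates = tuple(
        0.15 if nm == "x02" else (0.10 if nm == "x15" else 0.0) for nm in names
    )
    cfg = replace(cfg, missing_rates=rates, mar_drivers=("x00",))
    return inject_missingness(generate_cohort(cfg), cfg)


@pytest.fixture()
def tiny_table() -> CohortTable:
    """Hand-built two-hospital table for structural tests."""
    rng = np.random.default_rng(7)
    n = 40
    df = pd.DataFrame(
        {
            "record_id": [f"r{i:03d}" for i in range(n)],
            "hospital_id": ["A"] * 20 + ["B"] * 20,
            "outcome": rng.binomial(1, 0.4, n),
            "u": rng.normal(size=n),
            "v": rng.binomial(1, 0.5, n).astype(float),
        }
    )
    # guarantee both classes in both hospitals
    df.loc[0, "outcome"] = 1
    df.loc[1, "outcome"] = 0
    df.loc[20, "outcome"] = 1
    df.loc[21, "outcome"] = 0
    return CohortTable(df)
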