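from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fedsurv import SimConfig, build_federation, generate_cohort
from fedsurv.registry_model import CovariateBlock, ModelSpec, PatientRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_record(**overrides) -> PatientRecord:
    base = dict(
        patient_id="p1",
        tumour_sequence=1,
        topography="C02.1",
        morphology=8070,
        diagnosis_date=date(2010, 6, 15),
        vital_status="alive",
        end_date=date(2019, 1, 31),
        sex="male",
        age_at_diagnosis=55,
        stage="II",
        grade="moderate",
        treatment="surgery_only",
        hospital_id="h1",
        surgery=True,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def small_spec() -> ModelSpec:
    return ModelSpec(
        (
            CovariateBlock("country", ("TW", "NL"), "TW"),
            CovariateBlock("age_cat", ("lt60", "60_69", "ge70"), "lt60"),
            CovariateBlock("sex", ("female", "male"), "female"),
        ),
        label="small",
    )


@pytest.fixture(scope="session")
def small_cohorts() -> dict[str, pd.DataFrame]:
    cfg = SimConfig(n={"NL": 250, "TW": 550}, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def small_federation(small_cohorts):
    return build_federation(small_cohorts)


def pooled(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(tables.values(), ignore_index=True)


def split_sites(table: pd.DataFrame, n_sites: int, seed: int = 0) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, n_sites, len(table))
    return {f"site{i}": table[assignment == i].reset_index(drop=True) for i in range(n_sites)}
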