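import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from weighttte import default_params, load_toy_trial, simulate_cohort
from weighttte.simulate import Cohort


@pytest.fixture(scope="session")
def toy_subjects():
    return load_toy_trial()


@pytest.fixture(scope="session")
def default_cohort():
    """One default confounded cohort of 10,000 subjects (fixed seed)."""
    return simulate_cohort(default_params(), seed=101)


@pytest.fixture(scope="session")
def null_cohort():
    """Confounding switched off; true effects stay at 0 / 0.3."""
    return simulate_cohort(default_params().null_confounding(), seed=202)


def _subject_row(i: int, **over) -> dict:
    height = over.pop("height", 1.70)
    bmi0 = over.pop("bmi0", 27.0)
    weight0 = over.pop("weight0", bmi0 * height**2)
    row = {
        "id": i,
        "age0": 50.0,
        "sex": 0,
        "famhist": 0,
        "height": height,
        "weight0": weight0,
        "bmi0": bmi0,
        "smoking0": 0,
        "diuretics0": 0,
        "smoking1": 0,
        "diuretics1": 0,
        "chronic1": 0,
        "weight1": weight0,
        "change_category": "maintain",
        "event_interval": pd.NA,
    }
    row.update(over)
    return row


@pytest.fixture(scope="session")
def make_cohort():
    """Factory for small hand-built cohorts; rows are partial field dicts."""

    def build(rows: list[dict], **param_overrides) -> Cohort:
        params = default_params().replace(
            n_subjects=len(rows), **param_overrides
        )
        df = pd.DataFrame(
            [_subject_row(i + 1, **row) for i, row in enumerate(rows)]
        )
        df["event_interval"] = df["event_interval"].astype("Int64")
        cohort = Cohort(params=params, subjects=df, seed_used=0)
        cohort.validate()
        return cohort

    return build
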