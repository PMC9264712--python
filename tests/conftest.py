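import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from equicost.survey_data import ASSET_PREFIX, Dataset
from equicost.synthetic import default_config, generate_survey

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_dataset(
    n: int = 6,
    *,
    travel=None,
    waiting=None,
    consultation=None,
    transport=None,
    medical=None,
    ownership=None,
    level=None,
    service=None,
    residence=None,
    mode=None,
    assets=None,
) -> Dataset:
    """Small hand-specified dataset for unit tests."""
    rng = np.random.default_rng(1234)

    def col(values, default):
        return list(values) if values is not None else default

    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "facility_id": [f"f{i % 3}" for i in range(n)],
        "ownership": col(ownership, ["public"] * n),
        "level": col(level, ["dispensary"] * n),
        "service": col(service, ["anc"] * n),
        "residence": col(residence, ["rural"] * n),
        "travel_mode": col(mode, ["foot"] * n),
        "travel_time_min": col(travel, list(np.arange(n, dtype=float) * 10 + 5)),
        "waiting_time_min": col(waiting, [30.0] * n),
        "consultation_time_min": col(consultation, [10.0] * n),
        "transport_cost_tzs": col(transport, [0.0] * n),
        "medical_cost_tzs": col(medical, [0.0] * n),
        "insurance": [False] * n,
    })
    if assets is None:
        assets = rng.integers(0, 2, size=(n, 4)).astype(float)
        assets[0] = 0.0  # keep deterministic spread
        assets[-1] = 1.0
    assets = np.asarray(assets, dtype=float)
    names = []
    for j in range(assets.shape[1]):
        name = f"a{j}"
        df[ASSET_PREFIX + name] = assets[:, j]
        names.append(name)
    return Dataset(df=df, asset_names=names)


@pytest.fixture(scope="session")
def synth():
    """Study-scale synthetic survey with ground truth (fixed seed)."""
    return generate_survey(default_config(123), return_truth=True)


@pytest.fixture(scope="session")
def synth_dataset(synth):
    return synth[0]
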