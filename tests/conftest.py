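import numpy as np
import pandas as pd
import pytest

from panelnet import (
    CovariateSpec,
    FitConfig,
    ItemSpec,
    PanelDataset,
    ScenarioConfig,
    simulate_scenario,
)


def continuous_scenario(seed: int, **overrides) -> ScenarioConfig:
    """Continuous (non-ordinalized), covariate-free scenario for recovery
    harnesses; defaults to the standard recovery conditions."""
    base = dict(
        n=1000, p=10, density=0.2, sigma=0.5,
        covariates={}, ordinalize=False, missing_rate=0.0, seed=seed,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def small_completed_panel():
    """A small complete continuous panel with a fitted-network-friendly size."""
    data, truth = simulate_scenario(
        continuous_scenario(7, n=300, p=6, density=0.3, sigma=0.5)
    )
    return data, truth


@pytest.fixture(scope="session")
def study_panel():
    """One draw of the default study-scale scenario (ordinal, covariates,
    sparse MCAR missingness)."""
    data, truth = simulate_scenario(ScenarioConfig(seed=11))
    return data, truth


@pytest.fixture()
def tiny_panel():
    """Hand-built 4-subject, 2-item panel with one missing cell."""
    items = [ItemSpec("A", "Q", ("q1",), 0, 4), ItemSpec("B", "Q", ("q2",), 0, 4)]
    covs = [CovariateSpec("age", "continuous"), CovariateSpec("dx", "categorical")]
    return PanelDataset(
        subjects=["s1", "s2", "s3", "s4"],
        items=items,
        X1=np.array([[0.0, 1.0], [2.0, 3.0], [4.0, np.nan], [1.0, 2.0]]),
        X2=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [0.0, 4.0]]),
        covariates=pd.DataFrame(
            {"age": [30.0, 40.0, np.nan, 50.0],
             "dx": ["dep", "anx", "dep", "dep"]}
        ),
        covariate_specs=covs,
    )


def fast_fit() -> FitConfig:
    """CV config with a coarser grid for bootstrap-heavy tests."""
    return FitConfig(n_folds=5, n_lambdas=40)
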