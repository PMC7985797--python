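import numpy as np
import pandas as pd
import pytest

from geopersona.interval_model import fit_interval_re
from geopersona.lexicon import TRAITS
from geopersona.simulate import SimConfig, generate_panel


@pytest.fixture(scope="session")
def recovery_config() -> SimConfig:
    """Mid-size panel with a single planted trait effect and ~70% suppression."""
    return SimConfig(
        n_counties=500,
        n_years=3,
        seed=7,
        intercept_true=-8.0,
        beta_true={"neuroticism": 0.25},
        gamma_true={},
        sigma_u=2.0,
        sigma_e=3.0,
    )


@pytest.fixture(scope="session")
def recovery_panel(recovery_config) -> pd.DataFrame:
    latent, outcomes = generate_panel(recovery_config)
    return outcomes.merge(latent, on=["fips", "year"])


@pytest.fixture(scope="session")
def recovery_fit(recovery_panel):
    return fit_interval_re(recovery_panel, list(TRAITS))


def make_exact_sample_corr(n: int, R: np.ndarray, seed: int = 0) -> np.ndarray:
    """Data whose *sample* correlation matrix equals R exactly (columns z-scored).

    Draw, empirically whiten, then recolor with the Cholesky factor of R;
    closed-form psychometric identities can then be asserted to machine
    precision instead of within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    X = rng.standard_normal((n, k))
    X = X - X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    X = X @ np.linalg.inv(np.linalg.cholesky(S).T)
    X = X @ np.linalg.cholesky(R).T
    return X
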