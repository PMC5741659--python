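import numpy as np
import pandas as pd
import pytest

from stoichcorr import kinetics
from stoichcorr.profile_io import ProfileMatrix


@pytest.fixture(scope="session")
def toy_cycle():
    return kinetics.fixture_toy_cycle()


@pytest.fixture(scope="session")
def toy_ensemble(toy_cycle):
    """Seeded 50-draw steady-state ensemble of the mass-action toy cycle."""
    return kinetics.sample_ensemble(toy_cycle, n_draws=50, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)


def random_profile_matrix(rng, n_samples: int, n_metabolites: int) -> ProfileMatrix:
    names = [f"m{i:02d}" for i in range(n_metabolites)]
    values = pd.DataFrame(
        np.exp(rng.standard_normal((n_samples, n_metabolites))),
        index=[f"s{i}" for i in range(n_samples)],
        columns=names,
    )
    return ProfileMatrix(values)
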