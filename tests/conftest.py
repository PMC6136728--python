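import numpy as np
import pandas as pd
import pytest

from itcfit import (
    BayesianITC,
    SimulationSpec,
    mgedta_design,
    simulate_experiment,
)
from itcfit.sampler import PARAM_NAMES, PosteriorSamples


@pytest.fixture(scope="session")
def design():
    return mgedta_design()


@pytest.fixture(scope="session")
def noiseless_curve(design):
    """Heats simulated without noise or concentration error: truth == stated."""
    spec = SimulationSpec(concentration_cv=0.0, noise_sd=0.0, seed=0)
    q, truth = simulate_experiment(spec, design)
    return q, truth


@pytest.fixture(scope="session")
def noisy_curve(design):
    """One standard-conditions curve (10% concentration error, 1 ucal noise)."""
    spec = SimulationSpec(seed=20)
    q, truth = simulate_experiment(spec, design)
    return q, truth


@pytest.fixture(scope="session")
def general_posterior(design, noisy_curve):
    """A well-mixed General-model posterior for one simulated curve."""
    q, truth = noisy_curve
    model = BayesianITC(q, design, prior_model="general")
    return model.fit(
        n_samples=2000, thin=1000, seed=99, start="map", burn_in=300, adapt=True
    )


def make_samples(**columns) -> PosteriorSamples:
    """Build a PosteriorSamples from explicit per-parameter arrays.

    Unspecified parameters default to zeros (Ls/R0 to ones to stay
    positive); log_posterior defaults to zeros.
    """
    n = len(next(iter(columns.values())))
    data = {}
    for name in PARAM_NAMES:
        if name in columns:
            data[name] = np.asarray(columns[name], dtype=float)
        elif name in ("Ls", "R0"):
            data[name] = np.ones(n)
        else:
            data[name] = np.zeros(n)
    data["log_posterior"] = np.asarray(
        columns.get("log_posterior", np.zeros(n)), dtype=float
    )
    return PosteriorSamples(pd.DataFrame(data))
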