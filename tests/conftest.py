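import numpy as np
import pandas as pd
import pytest

import obslearn as ol
from obslearn.inference import ChainConfig


@pytest.fixture(scope="session")
def design():
    return ol.build_design()


@pytest.fixture(scope="session")
def small_design():
    """One sub-session, one block per condition: fast but structurally complete."""
    return ol.build_design(
        subsessions_per_visit=1, blocks_per_condition_per_subsession=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def micro_chains():
    """Tiny MCMC schedule for structural tests (not for recovery claims)."""
    return ChainConfig(n_chains=2, n_iterations=300, burn_in=100, thin=4)


@pytest.fixture(scope="session")
def toy_trials(small_design):
    """Two simulated subjects from model 3 under the small design."""
    rng = np.random.default_rng(7)
    ps = ol.ParameterSet(alpha=0.4, kappa=0.35, w=0.6, beta=7.0, rho=0.4, tau=2.0)
    tabs = [
        ol.simulate_observer(3, ps, small_design, rng, subject=f"s{i:02d}")
        for i in range(2)
    ]
    return pd.concat(tabs, ignore_index=True)


def relabel_all_vertex(trials: pd.DataFrame) -> pd.DataFrame:
    """Relabel every session as vertex, keeping blocks distinct per visit."""
    out = trials.copy()
    out["block"] = out["site"].astype(str) + ":" + out["block"].astype(str)
    out["site"] = "vertex"
    return out
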