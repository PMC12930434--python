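import numpy as np
import pytest

from methvar.hglm import RegionDesign
from methvar.simulate import ScenarioConfig, simulate_region, simulate_study


def make_region_design(n_cpgs, N, seed, delta=0.0, kappa=0.0, rho=0.3,
                       base_sd=1.0, var_design="full"):
    """Small stacked region design drawn from the compound-symmetry generator."""
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, N).astype(float)
    if np.unique(g).size < 2:
        g[0] = 1.0 - g[0]
    V = simulate_region(n_cpgs, N, g, rho, base_sd, delta, float(np.exp(kappa)), rng)
    y = V.T.reshape(-1)
    Xs = np.column_stack([np.ones(N), g])
    X = np.repeat(Xs, n_cpgs, axis=0)
    subject = np.repeat(np.arange(N), n_cpgs)
    Xv = np.ones((y.size, 1)) if var_design == "intercept" else X.copy()
    return RegionDesign(y=y, X_mean=X, X_var=Xv, subject=subject,
                        n_subjects=N, region_id="fixture")


@pytest.fixture
def small_rd():
    return make_region_design(4, 12, seed=2, delta=0.5, kappa=0.4)


@pytest.fixture(scope="session")
def tiny_study():
    """50-region mixed study used by several end-to-end tests."""
    cfg = ScenarioConfig(n_regions=50, prop_signal=0.2, scenario="DVMR",
                         mean_effect=1.0, var_fold=3.0, N=60,
                         group_props=(0.5, 0.5), seed=314)
    return simulate_study(cfg)
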