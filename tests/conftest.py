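import numpy as np
import pytest

import rateguard as rg


@pytest.fixture(scope="session")
def monod_cfg():
    return rg.monod_default()


@pytest.fixture(scope="session")
def nc_cfg():
    return rg.noncompetitive_default()


@pytest.fixture(scope="session")
def monod_traj(monod_cfg):
    return rg.simulate(monod_cfg)


@pytest.fixture(scope="session")
def nc_traj(nc_cfg):
    return rg.simulate(nc_cfg)


@pytest.fixture
def noise_free():
    """Noise spec with every CV at zero."""
    return rg.NoiseSpec(cv_biomass=0.0, cv_substrate=0.0, cv_volume=0.0,
                        cv_feed=0.0, seed=0)


def make_observed(t, X, interval=None):
    """Observed dataset with total biomass X at times t (V = 1 L)."""
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    return rg.ObservedDataset(
        t_sample=t, x_obs=X, S_obs=np.ones_like(t), V_obs=np.ones_like(t),
        uf_obs=np.zeros_like(t), Sf=400.0,
        interval=float(t[1] - t[0]) if interval is None else interval,
    )
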