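import numpy as np
import pytest

import pfaa_ssa as P
from pfaa_ssa.chamber import fit_ef_records, pool_isomers
from pfaa_ssa.scenarios import prepare_world_concentrations


@pytest.fixture(scope="session")
def scheme():
    return P.SizeFractionScheme()


@pytest.fixture(scope="session")
def chamber_campaign():
    """19 synthetic chamber experiments at the default study conditions."""
    cfg = P.SyntheticChamberConfig(seed=7)
    exps, truth = P.gen_chamber_experiments(cfg)
    return cfg, exps, truth


@pytest.fixture(scope="session")
def fitted_records(chamber_campaign, scheme):
    _, exps, _ = chamber_campaign
    pooled = pool_isomers(exps, ("L-PFOS", "B-PFOS"), "PFOS")
    return fit_ef_records(pooled, scheme, n_bootstrap=500, seed=7)


@pytest.fixture(scope="session")
def toy_world():
    return P.gen_grid_world(P.SyntheticWorldConfig(seed=11))


@pytest.fixture(scope="session")
def prepared_world(toy_world):
    """Toy world with merged raster and completed concentration table."""
    return prepare_world_concentrations(toy_world)


def brute_force_tls(x, y):
    """Independent minimizer of summed squared orthogonal distances for a
    line through the origin, parameterised by angle."""
    from scipy.optimize import minimize_scalar

    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def obj(theta):
        s = np.tan(theta)
        return float(np.sum((y - s * x) ** 2) / (1.0 + s * s))

    res = minimize_scalar(
        obj,
        bounds=(-np.pi / 2 + 1e-9, np.pi / 2 - 1e-9),
        method="bounded",
        options={"xatol": 1e-12},
    )
    # parabolic refinement of the numerical minimum in slope space
    s0 = float(np.tan(res.x))

    def obj_s(s):
        return float(np.sum((y - s * x) ** 2) / (1.0 + s * s))

    for h in (1e-5 * (1 + abs(s0)), 1e-7 * (1 + abs(s0))):
        f_m, f_0, f_p = obj_s(s0 - h), obj_s(s0), obj_s(s0 + h)
        denom = f_m - 2 * f_0 + f_p
        if denom > 0:
            s0 = s0 + 0.5 * h * (f_m - f_p) / denom
    return s0
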