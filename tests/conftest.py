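import dataclasses

import pytest

from feednet import engine, params as params_mod
from feednet.params import MeanSD


@pytest.fixture(scope="session")
def params():
    return params_mod.load_default_parameters()


@pytest.fixture(scope="session")
def corrs():
    return params_mod.load_default_correlations()


@pytest.fixture(scope="session")
def results_4k(params, corrs):
    """A moderate default-parameter run shared across summary/engine tests."""
    return engine.run_simulation(params, corrs, 4000, master_seed=11)


def degenerate_params(params):
    """All randomness off: zero SDs/scales, zero gains, zero health rates.

    Prices then collapse to their means (hence equal across endpoints) and
    the only difference between marketing at EP1 and later is cost.
    """
    zero = lambda ms: MeanSD(ms.mean, 0.0)
    return dataclasses.replace(
        params,
        corn_price=zero(params.corn_price),
        live_price=zero(params.live_price),
        dmi=zero(params.dmi),
        ep1_fbw=zero(params.ep1_fbw),
        ep1_hcw=zero(params.ep1_hcw),
        live_gain=MeanSD(0.0, 0.0),
        carcass_gain=MeanSD(0.0, 0.0),
        mort_rate=0.0,
        rem_rate=0.0,
        morb_rate=0.0,
        yg_intercepts=tuple((loc, 0.0) for loc, _ in params.yg_intercepts),
        qg_intercepts=tuple((loc, 0.0) for loc, _ in params.qg_intercepts),
        yg_betas=((0.0, 0.0),) * 3,
        qg_betas=((0.0, 0.0),) * 3,
    )
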