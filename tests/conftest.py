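import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phosphagen as pg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def printed_ic():
    """Published resting pools (mM)."""
    return pg.InitialConditions(atp0=2.16, argp0=7.5, arg0=3.3, pi0=3.8)


@pytest.fixture(scope="session")
def k_default():
    return pg.EquilibriumConstants(k_ad=1.0, k_ph=39.6)


@pytest.fixture(scope="session")
def thermo():
    return pg.ThermoConstants(delta_g0=-30.6, gas_constant=8.31445e-3, temperature=300.0)


@pytest.fixture(scope="session")
def rest_state(printed_ic, k_default):
    return pg.initial_state_from_equilibrium(printed_ic, k_default)


@pytest.fixture(scope="session")
def synth_terminal():
    return pg.gen_terminal_params(pg.GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def quiet_terminal(synth_terminal):
    """Terminal with zero per-AP costs: only the base rate consumes."""
    from dataclasses import replace
    return replace(synth_terminal, n_atp={c: 0.0 for c in pg.COMPONENTS})


def random_feasible_state(rng: np.random.Generator) -> pg.MetabolicState:
    """A random strictly positive metabolic state on physiological scales."""
    return pg.MetabolicState(
        atp=rng.uniform(0.1, 5.0),
        adp=rng.uniform(1e-4, 0.5),
        amp=rng.uniform(1e-6, 0.1),
        arg=rng.uniform(0.1, 10.0),
        argp=rng.uniform(0.1, 10.0),
        pi=rng.uniform(0.5, 18.0),
    )
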