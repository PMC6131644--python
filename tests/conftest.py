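"""Shared fixtures: reference cleft geometry and the expensive steady runs."""
import numpy as np
import pytest

import zincleft as z
from zincleft import fv


@pytest.fixture(scope="session")
def geom():
    # 3 um synapse with a 500 nm transmissive zone, 40 nm cleft
    return z.SynapseGeometry(R=500e-9, S=3e-6, h=40e-9)


@pytest.fixture(scope="session")
def transport():
    # 3x-hindered diffusion of free Zn2+ in the cleft
    return z.TransportParams(D=2e-10)


@pytest.fixture(scope="session")
def source():
    return z.SourceSpec(k=0.2)


@pytest.fixture(scope="session")
def tau(geom, transport):
    return z.slowest_time_constant(geom, transport.D_eff)


@pytest.fixture(scope="session")
def fine_profile(geom, transport, source):
    """Closed-form stationary profile on a grid fine enough that linear
    interpolation onto any FV grid is exact to ~1e-7 relative."""
    return z.stationary_profile(geom, source, transport, n_points=4096)


@pytest.fixture(scope="session")
def steady_runs(geom, transport, source, tau):
    """Constant-release FV runs integrated to quasi-steady state (12 tau)
    on a refinement ladder of grids.  Session-scoped: these carry most of
    the suite's runtime."""
    runs = {}
    for n in (150, 300, 600):
        runs[n] = fv.simulate(
            geom, transport, source, schedule=None, n_cells=n,
            t_end=12 * tau.tau_max, save_every=50000)
    return runs


@pytest.fixture(scope="session")
def decay_run(geom, transport, source, tau, fine_profile):
    """Free decay from the stationary profile (source switched off)."""
    return fv.simulate(
        geom, transport, z.SourceSpec(k=0.0), schedule=None, n_cells=600,
        t_end=2.5 * tau.tau_max, save_every=2000, c0=fine_profile)
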