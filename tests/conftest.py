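"""Shared fixtures: nominal lung model, published gains, expensive traces."""

import numpy as np
import pytest

import fracvent as fv


@pytest.fixture(scope="session")
def nominal():
    """(model, network) of the nominal 24-generation lung ladder."""
    return fv.nominal_model()


@pytest.fixture(scope="session")
def printed_gains():
    return fv.printed_gains_fixture()


@pytest.fixture(scope="session")
def nominal_closed_loop(nominal, printed_gains):
    model, _ = nominal
    return fv.assemble_closed_loop(model, printed_gains)


@pytest.fixture(scope="session")
def design_region():
    return fv.SectorDiskRegion.from_degrees(200.0, 5.0)


@pytest.fixture(scope="session")
def tracking_trace(nominal, printed_gains):
    """Two breath cycles of the published design at dt = 1 ms (shared: slow)."""
    model, _ = nominal
    profile = fv.VentilationProfile(n_cycles=2)
    glcfg = fv.GlConfig(dt=1e-3, t_end=profile.t_total)
    return (
        fv.simulate_closed_loop(model, printed_gains, profile, glcfg),
        profile,
    )


def kirchhoff_oracle(resistances, capacitances):
    """Brute-force nodal assembly of the ladder equations.

    Extracts A and B column-by-column by evaluating the per-node current
    balances D^a x_m = (i_{m-1} - i_m)/C_m at unit pseudo-states/input —
    an independent path to the same physics as the analytic assembly.
    """
    r = np.asarray(resistances, float)
    c = np.asarray(capacitances, float)
    n = r.size

    def derivative(x, u):
        currents = np.empty(n + 1)
        currents[0] = (u - x[0]) / r[0]
        for m in range(1, n):
            currents[m] = (x[m - 1] - x[m]) / r[m]
        currents[n] = 0.0  # last node has no outgoing branch
        return (currents[:-1] - currents[1:]) / c

    a = np.column_stack(
        [derivative(e, 0.0) for e in np.eye(n)]
    )
    b = derivative(np.zeros(n), 1.0).reshape(-1, 1)
    c_mat = np.zeros((1, n))
    c_mat[0, 0] = -1.0 / r[0]
    d = np.array([[1.0 / r[0]]])
    return a, b, c_mat, d
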