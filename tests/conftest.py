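import numpy as np
import pytest

from radiocell import nuclide_data, svalue_engine


@pytest.fixture(scope="session")
def lu177():
    return nuclide_data.load_chain("Lu-177")


@pytest.fixture(scope="session")
def ac225():
    return nuclide_data.load_chain("Ac-225")


@pytest.fixture(scope="session")
def reference_table():
    return svalue_engine.reference_svalue_table()


@pytest.fixture(scope="session")
def decay_matrix_factory():
    """Rate-matrix builder for ODE oracles: dN/dt = A N."""

    def build(chain):
        names = list(chain.names)
        lam = np.array([chain[n].decay_constant for n in names])
        a = np.diag(-lam)
        for i, n in enumerate(names):
            for dname, frac in chain[n].daughters:
                j = names.index(dname)
                a[j, i] += frac * lam[i]
        return names, lam, a

    return build
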