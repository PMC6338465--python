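import numpy as np
import pytest

from ratchetfit import conditions as C
from ratchetfit.kinetics import GeometryContext, RateSet
from ratchetfit.polymer import ForkParams
from ratchetfit.schemes import enumerate_schemes

#: canonical seed for the deterministic study fixtures
STUDY_SEED = 1


@pytest.fixture(scope="session")
def all_schemes():
    return enumerate_schemes()


@pytest.fixture(scope="session")
def rates_complex() -> RateSet:
    return C.rates_in_complex()


@pytest.fixture(scope="session")
def rates_isolated() -> RateSet:
    return C.rates_isolated()


@pytest.fixture(scope="session")
def geom_opposing() -> GeometryContext:
    return C.geometry_in_complex()


@pytest.fixture(scope="session")
def geom_hairpin() -> GeometryContext:
    return C.geometry_isolated()


@pytest.fixture(scope="session")
def small_study_traces():
    """A reduced two-geometry synthetic study shared across tests."""
    return C.make_study_traces(STUDY_SEED, n_traces=4)


@pytest.fixture(scope="session")
def small_study_dataset(small_study_traces):
    from ratchetfit.pipeline import process_traces

    return process_traces(small_study_traces)


@pytest.fixture(scope="session")
def fork_default() -> ForkParams:
    return ForkParams()


def exact_fv_dataset(scheme, rates, geometry, forces, atps, n=50):
    """Noiseless ForceVelocityDataset built from the analytic surface."""
    import pandas as pd

    from ratchetfit.kinetics import velocity_grid
    from ratchetfit.pipeline import ForceVelocityDataset

    rows = []
    for F in forces:
        for T in atps:
            v = float(velocity_grid(scheme, rates, F, T, geometry))
            rows.append({"geometry": geometry.mode, "atp": T, "f_bin": F,
                         "f_mean": F, "v_mean": v, "v_sem": 1.0, "n": n})
    return ForceVelocityDataset(table=pd.DataFrame(rows),
                                bin_edges=np.asarray(forces, dtype=float))
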