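import numpy as np
import pytest

from hfpbpk import (PBPKModel, PartitionSet, DrugParameters, apply_hf,
                    build_healthy, make_fixture)
from hfpbpk.reference_data import SYSTEMIC_TISSUES


@pytest.fixture(scope="session")
def healthy():
    return build_healthy()


@pytest.fixture(scope="session")
def hf_physiologies(healthy):
    return {cls: apply_hf(healthy, cls) for cls in ("II", "III", "IV")}


@pytest.fixture(scope="session")
def glycoside():
    """Digoxin-like renally cleared neutral fixture (fu_p drawn by seed)."""
    return make_fixture("renal_neutral_digoxin_like", seed=1)


@pytest.fixture(scope="session")
def glycoside_model(glycoside, healthy):
    return glycoside.to_model(healthy)


@pytest.fixture()
def uniform_toy_model(healthy):
    """Near-one-compartment toy: uniform partitions, renal-only clearance."""
    drug = DrugParameters(name="toy", cl_liver_int=0.0, cl_kidney_int=300.0,
                          fu_p=1.0, rb=1.0, peff=0.0, logp=0.0)
    ps = PartitionSet(ktp={t: 1.0 for t in list(SYSTEMIC_TISSUES) + ["lung"]},
                      method="override")
    return PBPKModel(physiology=healthy, drug=drug, partitions=ps)


def geometric_grid(t_end, n=300, t0=1.0 / 3600.0):
    """Output grid dense at early times (resolves the IV mixing spike)."""
    return np.unique(np.concatenate([[0.0], np.geomspace(t0, t_end, n)]))
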