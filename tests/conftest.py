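import numpy as np
import pytest

from hydrokin.core import MolecularSystem
from hydrokin.synthetic import build_two_domain_template


@pytest.fixture(scope="session")
def template() -> MolecularSystem:
    return build_two_domain_template()


def make_system(coords, names=None, elements=None, resids=None, resnames=None,
                record=None, chains=None):
    """Hand-rolled small system helper for geometric fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return MolecularSystem(
        names=np.asarray(names if names is not None else ["C"] * n),
        elements=np.asarray(elements if elements is not None else ["C"] * n),
        resids=np.asarray(resids if resids is not None else np.arange(1, n + 1)),
        resnames=np.asarray(resnames if resnames is not None else ["ALA"] * n),
        chains=np.asarray(chains if chains is not None else ["A"] * n),
        record=np.asarray(record if record is not None else ["protein"] * n),
        coords=coords,
    )
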