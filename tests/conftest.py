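import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from samplex.core import Atom, PerResidueData, Residue, ResidueKey, StructureEnsemble


def point_residue(chain: str, num: int, xyz, name="ALA", atom="CA", element="C") -> Residue:
    return Residue(
        key=ResidueKey(chain, num),
        name=name,
        atoms=[Atom(name=atom, element=element, coords=tuple(float(c) for c in xyz))],
    )


@pytest.fixture
def linear_chain():
    """Five single-atom residues on a line with 3 Å spacing."""
    return StructureEnsemble(
        [[point_residue("A", i + 1, (3.0 * i, 0.0, 0.0)) for i in range(5)]]
    )


@pytest.fixture
def nine_zeros_one_one():
    """The fully enumerable calibration dataset: nine 0s and a single 1."""
    values = {ResidueKey("A", i): 0.0 for i in range(1, 10)}
    values[ResidueKey("A", 10)] = 1.0
    return PerResidueData(values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
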