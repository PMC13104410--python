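import pytest
from hypothesis import HealthCheck, settings

from dockperm import Conformer, Atom, make_reference_ligand

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_ligand() -> Conformer:
    return make_reference_ligand(seed=7)


def toy_conformer(elements, coords, bonds=(), name="toy") -> Conformer:
    atoms = [Atom(e, tuple(map(float, c)), i) for i, (e, c) in enumerate(zip(elements, coords))]
    return Conformer(atoms=atoms, bonds=list(bonds), name=name)


@pytest.fixture
def water() -> Conformer:
    return toy_conformer(
        ["O", "H", "H"],
        [(0, 0, 0), (0.96, 0, 0), (-0.24, 0.93, 0)],
        [(0, 1, 1.0), (0, 2, 1.0)],
        name="water",
    )
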