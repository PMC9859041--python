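import numpy as np
import pytest

from tcrpmhc.geometry import DockingGeometry
from tcrpmhc.rmsd import GenericCdrComs
from tcrpmhc.structure import locate_core_residues
from tcrpmhc.synthetic import (
    SyntheticSpec,
    canonical_generic_coms,
    consensus_geometry,
    make_synthetic_complex,
    random_docking_geometry,
    random_synthetic_specs,
)
from tcrpmhc.templates import TemplateRecord


@pytest.fixture(scope="session")
def canonical_complex():
    return make_synthetic_complex(SyntheticSpec())


@pytest.fixture(scope="session")
def canonical_cores(canonical_complex):
    return locate_core_residues(canonical_complex)


@pytest.fixture(scope="session")
def coms() -> GenericCdrComs:
    return canonical_generic_coms()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_db():
    """20 random synthetic template records, deterministic."""
    specs = random_synthetic_specs(np.random.default_rng(11), 20)
    return [TemplateRecord.from_complex(make_synthetic_complex(s)) for s in specs]


def random_geometry_vectors(rng, n):
    """Well-conditioned random 6-vectors for round-trip style sweeps."""
    return np.column_stack([
        rng.uniform(18, 45, n),
        rng.uniform(-np.pi, np.pi, n),
        rng.uniform(0.05, 1.5, n),
        rng.uniform(-np.pi, np.pi, n),
        rng.uniform(0.05, 1.5, n),
        rng.uniform(-np.pi, np.pi, n),
    ])


@pytest.fixture()
def random_geometries(rng):
    return [
        DockingGeometry.from_vector(v)
        for v in random_geometry_vectors(rng, 50)
    ]
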