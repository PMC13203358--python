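import numpy as np
import pytest

from ppikit import synthetic_data as sd
from ppikit.structure_io import AtomRecord, Structure, infer_chem_roles


@pytest.fixture(scope="session")
def default_complex():
    """Base-frame toy complex of the packaged recipe (no jitter)."""
    structure, plant_geometry = sd.build_toy_complex(sd.default_recipe(seed=0))
    return structure, plant_geometry


@pytest.fixture(scope="session")
def default_ensemble():
    """One generated default ensemble with its ground-truth manifest."""
    return sd.generate_ensemble(sd.default_recipe(seed=0))


@pytest.fixture(scope="session")
def default_roles(default_ensemble):
    ens, _ = default_ensemble
    return infer_chem_roles(ens.topology)


def make_ion(serial, name, element, resid, chain, xyz, charge, eps=0.1,
             rmin_half=1.7, gb_radius=2.0, mass=20.0):
    return AtomRecord(serial, name, element, "ION", resid, chain,
                      np.asarray(xyz, float), mass, charge, eps, rmin_half,
                      gb_radius)


@pytest.fixture
def ion_pair_structure():
    """Oppositely charged two-partner ion pair, 3 A apart."""
    return Structure([make_ion(1, "NA", "NA", 1, "A", (0, 0, 0), 1.0),
                      make_ion(2, "CL", "CL", 1, "B", (3.0, 0, 0), -1.0)],
                     {"A": "A", "B": "B"})
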