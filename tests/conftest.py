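import numpy as np
import pytest

from ptmetad import (apply_numbering_offset, build_discriminating_contacts,
                     make_potential)
from ptmetad.synthetic import ToyKinaseSpec, make_toy_kinase_pair


@pytest.fixture(scope="session")
def toy_pair():
    """Synthetic two-state reference pair (pdb numbering) with ground truth."""
    spec = ToyKinaseSpec(seed=7)
    active, inactive, truth = make_toy_kinase_pair(spec)
    return active, inactive, truth


@pytest.fixture(scope="session")
def paper_pair(toy_pair):
    """The same pair in paper (signal-peptide) numbering."""
    active, inactive, _ = toy_pair
    return apply_numbering_offset(active), apply_numbering_offset(inactive)


@pytest.fixture(scope="session")
def contact_set(paper_pair):
    active, inactive = paper_pair
    return build_discriminating_contacts(active, inactive)


@pytest.fixture(scope="session")
def double_well_1d():
    return make_potential("double_well_1d", barrier=12.0)


def rigid_motion(coords, rng):
    """Random proper rotation + translation of an (n, 3) coordinate set."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(0, 2.0, 3)
    return coords @ rot.T + shift
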