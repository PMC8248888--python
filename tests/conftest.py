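"""Shared fixtures: tiny oracle structures and the standard weak dataset."""

import numpy as np
import pytest

from smipp.cell import AtomSite, Structure, UnitCell
from smipp.simulate import generate_structure, make_dataset, weak_scenario


@pytest.fixture(scope="session")
def toy_structure():
    """Five unequal atoms in a small cubic cell; quick direct summation."""
    rng = np.random.default_rng(42)
    cell = UnitCell(6.0, 6.0, 6.0)
    sites = [AtomSite(*rng.random(3), w=float(w))
             for w in (6.0, 7.0, 8.0, 6.0, 16.0)]
    return Structure(cell, sites)


@pytest.fixture(scope="session")
def weak_dataset():
    """The standard 30-atom weak-scatterer crystal with exact |E| data."""
    spec = weak_scenario(seed=11)
    structure = generate_structure(spec)
    refl, gt = make_dataset(structure, spec.d_min)
    return structure, refl, gt
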