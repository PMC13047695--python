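import numpy as np
import pytest

from cgnmr import fixtures, shiftnet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def peptide():
    """8-residue toy peptide with a GLY in the middle."""
    seq = ["ALA", "VAL", "LEU", "GLY", "SER", "PHE", "LYS", "THR"]
    return fixtures.make_toy_peptide(8, sequence=seq, seed=7)


@pytest.fixture
def teacher():
    return fixtures.make_teacher_model(seed=3)


@pytest.fixture
def featurizer(peptide):
    return shiftnet.Featurizer(peptide)


def finite_difference_forces(energy_fn, coords, h=1e-6):
    """Central-difference −∇E for testing force providers."""
    coords = np.asarray(coords, float)
    forces = np.zeros_like(coords)
    for k in range(coords.shape[0]):
        for d in range(3):
            cp = coords.copy()
            cm = coords.copy()
            cp[k, d] += h
            cm[k, d] -= h
            forces[k, d] = -(energy_fn(cp) - energy_fn(cm)) / (2 * h)
    return forces


def max_relative_error(actual, expected, floor=1e-4):
    actual = np.asarray(actual, float)
    expected = np.asarray(expected, float)
    scale = max(np.max(np.abs(expected)), floor)
    return np.max(np.abs(actual - expected)) / scale
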