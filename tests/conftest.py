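import numpy as np
import pytest

from idrkit import (
    CDSpectrum,
    MRE,
    MILLIDEGREES,
    SampleMeta,
    default_basis,
)


@pytest.fixture
def grid():
    return np.arange(190.0, 251.0)


@pytest.fixture
def meta():
    return SampleMeta(pathlength_cm=0.1, molarity=10e-6, n_peptide_bonds=111)


@pytest.fixture
def basis(grid):
    return default_basis(grid)


@pytest.fixture
def flat_mdeg(grid):
    """A constant 5 mdeg spectrum, handy for arithmetic checks."""
    return CDSpectrum(grid, np.full(grid.size, 5.0), MILLIDEGREES)


def mre_spectrum(basis, fractions):
    """Noiseless MRE spectrum of a known fractional mixture."""
    return CDSpectrum(basis.wavelengths, basis.combine(fractions), MRE)
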