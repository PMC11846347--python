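"""Shared fixtures: small synthetic spectra and cohorts, all seeded."""

import numpy as np
import pytest

from imfstat import SpectraMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """2 subjects x 3 wavenumbers."""
    return SpectraMatrix(
        ["A", "B"],
        np.array([1000.0, 1004.0, 1008.0]),
        np.array([[1.0, 2.0, 3.0], [0.5, 0.25, 0.125]]),
    )


def make_matrix(rng, n=20, wavenumbers=None, loc=0.0):
    """Random spectra helper used across test modules."""
    if wavenumbers is None:
        wavenumbers = 1000.0 + 4.0 * np.arange(50)
    ab = rng.normal(loc, 1.0, size=(n, len(wavenumbers))) + 5.0
    ids = [f"S{i}" for i in range(n)]
    return SpectraMatrix(ids, np.asarray(wavenumbers, float), ab)
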