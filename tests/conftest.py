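"""Shared fixtures: study conditions for the three radiation regimes.

All test data is generated at run time by the forward simulator; nothing is
read from disk.  The study conditions themselves (cells, spectra, detector
geometries, indexer parameters) are the package's canonical ones from
``snapindex.studies``; docs/methods.md states the rationale for each.
"""

import numpy as np
import pytest

from snapindex.simulate import DEFAULT_GEOMETRY, simulate_pattern
from snapindex.studies import (
    CELL_ORTHO,
    CELL_PINK,
    CELL_TRICLINIC,
    ELECTRON,
    ELECTRON_GEOMETRY,
    MONO,
    MONO_PARAMS,
    PINK,
    PINK_PARAMS,
    electron_config,
    mono_config,
    pink_config,
)

__all__ = [
    "CELL_ORTHO",
    "CELL_PINK",
    "CELL_TRICLINIC",
    "ELECTRON",
    "ELECTRON_GEOMETRY",
    "MONO",
    "MONO_PARAMS",
    "PINK",
    "PINK_PARAMS",
    "DEFAULT_GEOMETRY",
    "electron_config",
    "mono_config",
    "pink_config",
]


@pytest.fixture(scope="session")
def mono_pattern():
    """One noise-free monochromatic snapshot with ground truth."""
    return simulate_pattern(mono_config(seed=7))


@pytest.fixture(scope="session")
def pink_pattern():
    """One noise-free pink-beam snapshot with ground truth."""
    return simulate_pattern(pink_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
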