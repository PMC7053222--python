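"""Canonical study conditions for the three radiation regimes.

These are the fixed experimental conditions used by the package's evaluation
protocols (test suite and the reproduction script): cells, spectra, detector
geometries and the indexing parameters appropriate to each regime.  The
rationale for each choice — cell sizes, resolution cutoffs, spectral shapes,
grid sizes — is laid out in docs/methods.md.
"""

from __future__ import annotations

from .geometry import ExperimentGeometry, UnitCell
from .indexer import IndexerParams
from .simulate import SimulationConfig, SpectrumModel

__all__ = [
    "CELL_ORTHO",
    "CELL_PINK",
    "CELL_TRICLINIC",
    "MONO",
    "PINK",
    "ELECTRON",
    "ELECTRON_GEOMETRY",
    "MONO_PARAMS",
    "PINK_PARAMS",
    "mono_config",
    "pink_config",
    "electron_config",
]

#: orthorhombic protein-sized cell: monochromatic and electron studies
CELL_ORTHO = UnitCell(50.0, 60.0, 70.0, 90.0, 90.0, 90.0)

#: small orthorhombic cell for the pink-beam study — candidate multiplicity
#: scales with cell volume x q^3 x bandwidth, so the 25% tail band pairs
#: with a small cell at higher resolution (see docs/methods.md)
CELL_PINK = UnitCell(25.0, 30.0, 35.0, 90.0, 90.0, 90.0)

CELL_TRICLINIC = UnitCell(73.0, 81.0, 95.0, 83.0, 97.0, 104.0)

#: monochromatic ~1 A X-rays (zero-bandwidth limit; excitation-error model)
MONO = SpectrumModel(lambda_nominal_A=1.0, shape="flat", fwhm_fraction=0.0)

#: pink beam: 5% FWHM Gaussian with tails extending to 25% of the nominal
PINK = SpectrumModel(
    lambda_nominal_A=1.0,
    shape="gaussian_with_tails",
    fwhm_fraction=0.05,
    tail_extent_fraction=0.25,
)

#: electrons: 0.025 A de Broglie wavelength, nearly flat Ewald sphere
ELECTRON = SpectrumModel(lambda_nominal_A=0.025, shape="flat", fwhm_fraction=0.0)

#: long camera length so the small electron scattering angles span the panel
ELECTRON_GEOMETRY = ExperimentGeometry(
    detector_distance_mm=1900.0,
    pixel_size_mm=0.1,
    beam_center_px=(999.5, 999.5),
    detector_shape_px=(2000, 2000),
)

#: indexing parameters for the narrow-band regimes (dense preset grid)
MONO_PARAMS = IndexerParams(angle_resolution="dense")

#: pink-beam indexing: vote on the spectral core with a finer grid; every
#: supplied peak is considered so the multiplicity-ordered admission has the
#: full set of sparse voters to draw from
PINK_PARAMS = IndexerParams(
    angle_resolution="balanced",
    core_bandwidth=0.08,
    grid_n_override=201,
    considered_peaks_count=60,
)


def mono_config(seed: int, **kw) -> SimulationConfig:
    """Monochromatic study snapshot: 50/60/70 A cell to 4 A resolution."""
    kw.setdefault("q_cutoff", 0.25)
    return SimulationConfig(cell=CELL_ORTHO, spectrum=MONO, seed=seed, **kw)


def pink_config(seed: int, **kw) -> SimulationConfig:
    """Pink-beam study snapshot: 25/30/35 A cell to 2 A resolution."""
    kw.setdefault("q_cutoff", 0.5)
    kw.setdefault("wilson_b_A2", 15.0)
    return SimulationConfig(cell=CELL_PINK, spectrum=PINK, seed=seed, **kw)


def electron_config(seed: int, **kw) -> SimulationConfig:
    """Electron study snapshot: 50/60/70 A cell, long camera length."""
    kw.setdefault("q_cutoff", 0.25)
    kw.setdefault("geometry", ELECTRON_GEOMETRY)
    return SimulationConfig(cell=CELL_ORTHO, spectrum=ELECTRON, seed=seed, **kw)
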