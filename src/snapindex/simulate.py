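"""Forward simulation of snapshot diffraction peak lists with ground truth.

The simulator is the package's test bed: it produces exactly the peak-list
format the indexer consumes, together with the true crystal orientation(s)
and per-spot Miller indices and excitation wavelengths, across the three
regimes of interest:

* monochromatic X-rays (~1 Angstrom): an excitation-error model — RLPs
  within a small distance of the nominal Ewald sphere diffract, standing in
  for mosaic spread, divergence and residual bandwidth;
* pink-beam X-rays: a wavelength-band model (Gaussian spectrum of ~5% FWHM
  with tails extending to ~25% of the nominal wavelength);
* electrons (lambda ~ 0.01-0.03 Angstrom, a nearly flat Ewald sphere; the
  wavelength is supplied directly, no accelerating-voltage conversion) —
  the same excitation-error model, which there plays the role of the
  crystal-shape-transform ("relrod") excitation.

Intensities follow an exponential law scaled by the spectral weight and a
Wilson temperature factor, with a detection threshold below which a
reflection goes unobserved; intensities influence which peaks the indexer
ranks highest, never geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erf

from .errors import DegenerateSimulationError
from .geometry import (
    ExperimentGeometry,
    UnitCell,
    WavelengthBand,
    cell_to_reciprocal_basis,
    generate_rlps,
    wavelength_of_q,
)
from .rotations import Rotation, random_rotation

__all__ = [
    "SpectrumModel",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedPattern",
    "DEFAULT_GEOMETRY",
    "random_orientation",
    "spectrum_density",
    "simulate_pattern",
    "rotation_series",
]

#: Default detector: 2000 x 2000 pixels of 0.1 mm at 100 mm, beam centred.
#: A ~50-70 Angstrom protein cell at ~1 Angstrom then yields tens to a few
#: hundred spots per snapshot, matching typical serial-crystallography frames.
DEFAULT_GEOMETRY = ExperimentGeometry(
    detector_distance_mm=100.0,
    pixel_size_mm=0.1,
    beam_center_px=(999.5, 999.5),
    detector_shape_px=(2000, 2000),
)


@dataclass(frozen=True)
class SpectrumModel:
    """Incident spectrum over wavelength, normalized on its band.

    ``flat`` is a top-hat of relative full width ``fwhm_fraction``;
    ``gaussian_with_tails`` is a Gaussian of the stated FWHM truncated at
    ``tail_extent_fraction`` (relative full width of the tails) and
    renormalized.  The band handed to the indexer is the full (tail-extended)
    band.
    """

    lambda_nominal_A: float
    shape: str = "flat"
    fwhm_fraction: float = 0.0
    tail_extent_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("flat", "gaussian_with_tails"):
            raise ValueError("shape must be 'flat' or 'gaussian_with_tails'")
        if self.tail_extent_fraction is None:
            object.__setattr__(self, "tail_extent_fraction", self.fwhm_fraction)
        if self.tail_extent_fraction < self.fwhm_fraction:
            raise ValueError("tail_extent_fraction must be >= fwhm_fraction")

    @property
    def band(self) -> WavelengthBand:
        """Full wavelength band (tails included)."""
        lam = self.lambda_nominal_A
        half = 0.5 * self.tail_extent_fraction
        return WavelengthBand(lam * (1.0 - half), lam * (1.0 + half), lam)

    def density(self, lam: np.ndarray) -> np.ndarray:
        """Normalized spectral density at wavelengths ``lam`` (0 outside band)."""
        lam = np.asarray(lam, dtype=float)
        band = self.band
        width = band.lambda_max_A - band.lambda_min_A
        inside = (lam >= band.lambda_min_A) & (lam <= band.lambda_max_A)
        if self.shape == "flat" or self.fwhm_fraction == 0.0:
            if width == 0.0:
                return np.where(lam == band.lambda_nominal_A, 1.0, 0.0)
            return np.where(inside, 1.0 / width, 0.0)
        sigma = self.fwhm_fraction * self.lambda_nominal_A / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        z = (lam - self.lambda_nominal_A) / sigma
        gauss = np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))
        zmax = 0.5 * width / sigma
        norm = erf(zmax / np.sqrt(2.0))  # mass inside the truncation
        return np.where(inside, gauss / norm, 0.0)


def spectrum_density(lam: np.ndarray, model: SpectrumModel) -> np.ndarray:
    """Functional alias for :meth:`SpectrumModel.density`."""
    return model.density(lam)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one snapshot pattern deterministically."""

    cell: UnitCell
    spectrum: SpectrumModel
    geometry: ExperimentGeometry = DEFAULT_GEOMETRY
    orientations: tuple[Rotation, ...] | None = None  # None -> random per crystal
    n_crystals: int = 1
    peak_jitter_px: float = 0.0
    spurious_fraction: float = 0.0
    missing_fraction: float = 0.0
    q_cutoff: float = 0.2
    seed: int = 0
    #: excitation-error tolerance (1/Angstrom) used when the band is exactly
    #: monochromatic: RLPs within this distance of the nominal Ewald sphere
    #: diffract, and the spot appears where the sphere meets the smeared RLP.
    #: Emulates mosaic spread, beam divergence and residual bandwidth for
    #: X-rays, and the crystal-shape-transform ("relrod") excitation for
    #: electrons; without it the sphere is a zero-measure surface and a
    #: strictly monochromatic simulation would never excite any RLP.
    excitation_error_invA: float = 1e-3
    #: Wilson temperature factor (Angstrom^2): mean intensities decay as
    #: exp(-B q^2 / 2).  Makes the brightest peaks predominantly
    #: low-resolution, as in real data, which is what intensity-ranked peak
    #: selection for the voting stage relies on.
    wilson_b_A2: float = 30.0
    #: detection threshold, in units of the mean intensity of an unattenuated
    #: reflection: a reflection is observed iff its drawn intensity exceeds
    #: this.  Reflections excited in faint spectral tails or at high
    #: resolution thus drop out of the peak list, as they do in real data.
    detection_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("spurious_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.orientations is not None and len(self.orientations) != self.n_crystals:
            raise ValueError("orientations must match n_crystals")


@dataclass
class GroundTruth:
    """True orientations and per-spot provenance of a simulated pattern.

    ``spot_*`` arrays are aligned with the emitted peak list; spurious peaks
    have ``spot_crystal == -1`` and no hkl/wavelength information.
    """

    rotations: list[Rotation]
    spot_crystal: np.ndarray  # (n,) int, -1 for spurious
    spot_hkl: np.ndarray  # (n, 3) int, 0 for spurious
    spot_lambda: np.ndarray  # (n,) Angstrom, NaN for spurious
    spot_true_xy: np.ndarray  # (n, 2) px before jitter, NaN for spurious

    @property
    def n_lattice_peaks(self) -> int:
        return int((self.spot_crystal >= 0).sum())

    @property
    def n_spurious(self) -> int:
        return int((self.spot_crystal < 0).sum())


@dataclass
class SimulatedPattern:
    """A simulated peak list plus its ground truth."""

    peaks: np.ndarray  # (n, 3) x_px, y_px, intensity
    truth: GroundTruth
    config: SimulationConfig


def random_orientation(rng: np.random.Generator) -> Rotation:
    """Rotation drawn uniformly from the invariant (Haar) measure."""
    return random_rotation(rng)


def _project(q: np.ndarray, lam: np.ndarray, geom: ExperimentGeometry):
    n = lam[:, None] * q
    n[:, 2] += 1.0
    x_px = n[:, 0] / n[:, 2] * geom.detector_distance_mm / geom.pixel_size_mm + geom.beam_center_px[0]
    y_px = n[:, 1] / n[:, 2] * geom.detector_distance_mm / geom.pixel_size_mm + geom.beam_center_px[1]
    return x_px, y_px, n[:, 2] > 1e-9


def simulate_pattern(config: SimulationConfig) -> SimulatedPattern:
    """Simulate one snapshot pattern with full ground truth.

    Per crystal: orient the reciprocal lattice; keep RLPs whose elastic
    wavelength lies in the spectrum band, thinned with probability
    proportional to the spectral density; project onto the detector; merge
    spots closer than 1 px (positions averaged, intensities summed); apply
    Gaussian positional jitter; drop a ``missing_fraction`` at random; append
    uniformly placed spurious peaks; shuffle.

    Raises
    ------
    DegenerateSimulationError
        If no reflection survives (cell/band/detector mismatch).
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    basis0 = cell_to_reciprocal_basis(config.cell)
    band = config.spectrum.band
    dens_max = float(np.max(config.spectrum.density(
        np.linspace(band.lambda_min_A, band.lambda_max_A, 4097)
    ))) if not band.is_monochromatic else 1.0

    rotations: list[Rotation] = []
    rows = []  # (x, y, intensity, crystal, h, k, l, lambda)
    for ic in range(config.n_crystals):
        rot = (
            config.orientations[ic]
            if config.orientations is not None
            else random_orientation(rng)
        )
        rotations.append(rot)
        basis = basis0.rotated(rot.as_matrix())
        rlps = generate_rlps(basis, config.q_cutoff)
        if band.is_monochromatic:
            # excitation-error model: keep RLPs within xi of the nominal
            # sphere; the spot sits where the sphere cuts the smeared RLP
            lam_n = band.lambda_nominal_A
            v = rlps.q0.copy()
            v[:, 2] += 1.0 / lam_n
            s = np.linalg.norm(v, axis=1) - 1.0 / lam_n
            keep = np.abs(s) <= config.excitation_error_invA
            q, hkl = rlps.q0[keep], rlps.hkl[keep]
            lam = np.full(len(q), lam_n)
            weight = np.ones(len(q))
            n = v[keep] / np.linalg.norm(v[keep], axis=1, keepdims=True)
            fwd = n[:, 2] > 1e-9
            x_px = (
                n[:, 0] / np.where(fwd, n[:, 2], 1.0) * geom.detector_distance_mm / geom.pixel_size_mm
                + geom.beam_center_px[0]
            )
            y_px = (
                n[:, 1] / np.where(fwd, n[:, 2], 1.0) * geom.detector_distance_mm / geom.pixel_size_mm
                + geom.beam_center_px[1]
            )
        else:
            lam = wavelength_of_q(rlps.q0)
            keep = (lam > 0) & (lam >= band.lambda_min_A) & (lam <= band.lambda_max_A)
            q, hkl, lam = rlps.q0[keep], rlps.hkl[keep], lam[keep]
            weight = config.spectrum.density(lam) / dens_max
            x_px, y_px, fwd = _project(q, lam, geom)
        nx, ny = geom.detector_shape_px
        on = fwd & (x_px >= 0) & (x_px <= nx - 1) & (y_px >= 0) & (y_px <= ny - 1)
        # intensity: exponential law x spectral weight x Wilson falloff;
        # only reflections above the detection threshold are observed
        wilson = np.exp(
            -0.5 * config.wilson_b_A2 * np.einsum("ij,ij->i", q[on], q[on])
        )
        intensity = rng.exponential(1.0, size=int(on.sum())) * weight[on] * wilson
        detected = intensity > config.detection_threshold
        sel = np.flatnonzero(on)[detected]
        intensity = intensity[detected]
        for j, i_full in enumerate(sel):
            rows.append(
                (
                    x_px[i_full],
                    y_px[i_full],
                    intensity[j],
                    ic,
                    int(hkl[i_full, 0]),
                    int(hkl[i_full, 1]),
                    int(hkl[i_full, 2]),
                    lam[i_full],
                )
            )
    if not rows:
        raise DegenerateSimulationError(
            "simulation produced zero reflections; check cell, band and detector"
        )
    arr = np.array(rows, dtype=float)

    # merge spots within 1 px: same rounded pixel cell -> one observed peak,
    # position average, intensities summed, provenance of the brightest member
    key = np.round(arr[:, 0]).astype(np.int64) * 1_000_003 + np.round(arr[:, 1]).astype(np.int64)
    order = np.argsort(key, kind="stable")
    arr = arr[order]
    key = key[order]
    merged = []
    start = 0
    for end in range(1, len(arr) + 1):
        if end == len(arr) or key[end] != key[start]:
            block = arr[start:end]
            pos = block[:, :2].mean(axis=0)
            inten = block[:, 2].sum()
            lead = block[np.argmax(block[:, 2])]
            merged.append(np.concatenate([pos, [inten], lead[3:]]))
            start = end
    arr = np.vstack(merged)

    # positional jitter, then random omissions
    if config.peak_jitter_px > 0:
        arr[:, 0:2] = arr[:, 0:2] + rng.normal(0.0, config.peak_jitter_px, size=(len(arr), 2))
    if config.missing_fraction > 0:
        keep = rng.random(len(arr)) >= config.missing_fraction
        if keep.sum() == 0:
            keep[rng.integers(len(arr))] = True
        arr = arr[keep]

    n_true = len(arr)

    # spurious peaks uniform on the detector; intensity scale matched to the
    # lattice peaks so intensity ranking cannot trivially exclude them
    n_spur = int(round(config.spurious_fraction / (1.0 - config.spurious_fraction) * n_true))
    if n_spur:
        nx, ny = geom.detector_shape_px
        sx = rng.uniform(0, nx - 1, n_spur)
        sy = rng.uniform(0, ny - 1, n_spur)
        scale = float(np.median(arr[:, 2]))
        si = rng.exponential(max(scale, 1e-12), n_spur)
        spur = np.column_stack(
            [sx, sy, si, -np.ones(n_spur), np.zeros((n_spur, 3)), np.full(n_spur, np.nan)]
        )
        arr = np.vstack([arr, spur])

    perm = rng.permutation(len(arr))
    arr = arr[perm]

    truth = GroundTruth(
        rotations=rotations,
        spot_crystal=arr[:, 3].astype(int),
        spot_hkl=arr[:, 4:7].astype(int),
        spot_lambda=arr[:, 7],
        spot_true_xy=_true_positions(arr, rotations, config, geom),
    )
    peaks = np.ascontiguousarray(arr[:, :3])
    return SimulatedPattern(peaks=peaks, truth=truth, config=config)


def _true_positions(
    arr: np.ndarray,
    rotations: list[Rotation],
    config: SimulationConfig,
    geom: ExperimentGeometry,
) -> np.ndarray:
    """Exact detector positions recomputed from each spot's provenance."""
    out = np.full((len(arr), 2), np.nan)
    crystal = arr[:, 3].astype(int)
    basis0 = cell_to_reciprocal_basis(config.cell)
    band = config.spectrum.band
    for ic in np.unique(crystal[crystal >= 0]):
        idx = np.flatnonzero(crystal == ic)
        basis = basis0.rotated(rotations[ic].as_matrix())
        q = arr[idx, 4:7] @ basis.rows
        if band.is_monochromatic:
            v = q.copy()
            v[:, 2] += 1.0 / band.lambda_nominal_A
            n = v / np.linalg.norm(v, axis=1, keepdims=True)
            x_px = n[:, 0] / n[:, 2] * geom.detector_distance_mm / geom.pixel_size_mm + geom.beam_center_px[0]
            y_px = n[:, 1] / n[:, 2] * geom.detector_distance_mm / geom.pixel_size_mm + geom.beam_center_px[1]
        else:
            lam = wavelength_of_q(q)
            x_px, y_px, _ = _project(q, lam, geom)
        out[idx, 0] = x_px
        out[idx, 1] = y_px
    return out


def rotation_series(
    config: SimulationConfig,
    delta_deg: float,
    n_frames: int,
    axis: np.ndarray = (1.0, 0.0, 0.0),
) -> list[SimulatedPattern]:
    """Simulate a goniometer-style rotation series, one snapshot per frame.

    Frame ``k`` has orientation ``R_axis(k * delta) o R0`` with everything
    else identical; each frame is indexed independently by the caller (the
    serial treatment of a rotation series).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if config.n_crystals != 1:
        raise ValueError("rotation series supports a single crystal")
    rng = np.random.default_rng(config.seed)
    r0 = (
        config.orientations[0]
        if config.orientations is not None
        else random_orientation(rng)
    )
    frames = []
    for k in range(n_frames):
        rk = Rotation.from_axis_angle(np.asarray(axis, dtype=float), np.radians(k * delta_deg)) @ r0
        cfg_k = replace(config, orientations=(rk,), seed=config.seed + 1000 + k)
        frames.append(simulate_pattern(cfg_k))
    return frames
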