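"""Diffraction geometry: detector, wavelength band, unit cell and reciprocal space.

This module converts observed Bragg-peak positions on a flat detector into
*uncertainty line segments* (ULS) in reciprocal space and enumerates the
reciprocal-lattice points (RLPs) of a known unit cell that could have produced
each peak.

Conventions (fixed for the whole package):

* Lab frame: the incident beam travels along ``+z``.  The detector is a plane
  perpendicular to ``z`` at ``z = detector_distance``, with detector ``x, y``
  axes parallel to the lab ``x, y`` axes.  Detector coordinates are pixel
  centers.
* Reciprocal space uses the crystallographic ``|q| = 1/d`` convention (no
  factor of 2*pi), so the Ewald sphere has radius ``1/lambda``.
* For a scattering direction ``n`` (unit vector) and wavelength ``lambda`` the
  momentum transfer is ``q = (n - z) / lambda``.  With an unknown wavelength
  inside a band ``[lambda_min, lambda_max]`` the possible ``q`` form a radial
  line segment through the origin -- the ULS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegeneratePeakError,
    InvalidCellError,
    ResourceLimitError,
)

__all__ = [
    "ExperimentGeometry",
    "WavelengthBand",
    "UnitCell",
    "ReciprocalBasis",
    "PeakObservation",
    "UncertaintyLineSegment",
    "ReciprocalLatticePoint",
    "RlpSet",
    "cell_to_reciprocal_basis",
    "pixel_to_direction",
    "pixels_to_directions",
    "build_uls",
    "build_ulss",
    "generate_rlps",
    "candidate_rlps",
    "wavelength_of_q",
]

#: Unit vector of the incident beam in the lab frame.
BEAM_DIRECTION = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class ExperimentGeometry:
    """Flat single-panel detector geometry.

    Parameters
    ----------
    detector_distance_mm:
        Sample-to-detector distance along the beam, millimetres.
    pixel_size_mm:
        Edge length of a (square) pixel, millimetres.
    beam_center_px:
        Detector coordinates (pixels) where the direct beam would hit.
    detector_shape_px:
        Number of pixels along detector x and y.
    """

    detector_distance_mm: float
    pixel_size_mm: float
    beam_center_px: tuple[float, float]
    detector_shape_px: tuple[int, int] = (2000, 2000)

    def __post_init__(self) -> None:
        if self.detector_distance_mm <= 0:
            raise ValueError("detector_distance_mm must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")


@dataclass(frozen=True)
class WavelengthBand:
    """Wavelength range of the incident beam, in Angstrom.

    The monochromatic case is ``lambda_min == lambda_max``.
    """

    lambda_min_A: float
    lambda_max_A: float
    lambda_nominal_A: float

    def __post_init__(self) -> None:
        if not (0 < self.lambda_min_A <= self.lambda_nominal_A <= self.lambda_max_A):
            raise ValueError(
                "require 0 < lambda_min <= lambda_nominal <= lambda_max, got "
                f"({self.lambda_min_A}, {self.lambda_nominal_A}, {self.lambda_max_A})"
            )

    @classmethod
    def monochromatic(cls, lam: float) -> "WavelengthBand":
        return cls(lam, lam, lam)

    @property
    def is_monochromatic(self) -> bool:
        return self.lambda_min_A == self.lambda_max_A

    def contains(self, lam: np.ndarray, tolerance: float = 0.0) -> np.ndarray:
        """Elementwise test for wavelengths inside the (tolerance-widened) band."""
        lam = np.asarray(lam)
        return (lam >= self.lambda_min_A * (1.0 - tolerance)) & (
            lam <= self.lambda_max_A * (1.0 + tolerance)
        )


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        # triangle-like condition: the metric tensor must be positive definite
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise InvalidCellError("cell angles violate the metric positivity condition")

    def real_basis(self) -> np.ndarray:
        """Real-space basis vectors as rows (Angstrom), canonical placement.

        ``a`` lies along ``+x``; ``b`` lies in the ``xy`` plane with positive
        ``y`` component; ``c`` completes a right-handed set.
        """
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        v = np.sqrt(v2)
        a1 = np.array([self.a, 0.0, 0.0])
        a2 = np.array([self.b * cg, self.b * sg, 0.0])
        a3 = np.array([self.c * cb, self.c * (ca - cb * cg) / sg, self.c * v / sg])
        return np.vstack([a1, a2, a3])

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return float(abs(np.linalg.det(self.real_basis())))


@dataclass(frozen=True)
class ReciprocalBasis:
    """Reciprocal basis vectors as rows of a 3x3 matrix, lab frame, 1/Angstrom.

    Satisfies ``B @ A.T = I`` where ``A`` holds the real-space basis rows, i.e.
    a reflection with Miller indices ``(h, k, l)`` sits at
    ``q = h*b1 + k*b2 + l*b3 = hkl @ rows``.
    """

    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (3, 3):
            raise ValueError("reciprocal basis must be a 3x3 matrix")
        if abs(np.linalg.det(rows)) < 1e-300:
            raise ValueError("reciprocal basis is singular")
        object.__setattr__(self, "rows", rows)

    def rotated(self, rotation_matrix: np.ndarray) -> "ReciprocalBasis":
        """Basis with every reciprocal vector rotated by the given matrix."""
        return ReciprocalBasis(self.rows @ np.asarray(rotation_matrix).T)

    def q_of_hkl(self, hkl: np.ndarray) -> np.ndarray:
        """Positions ``q`` (..., 3) of Miller-index triples (..., 3)."""
        return np.asarray(hkl, dtype=float) @ self.rows

    def real_rows(self) -> np.ndarray:
        """Real-space basis rows ``A`` recovered from ``B @ A.T = I``."""
        return np.linalg.inv(self.rows).T

    def cell_parameters(self) -> UnitCell:
        """Unit-cell parameters implied by this basis."""
        a_rows = self.real_rows()
        la, lb, lc = np.linalg.norm(a_rows, axis=1)

        def ang(u, v):
            return float(
                np.degrees(
                    np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
                )
            )

        return UnitCell(
            la, lb, lc, ang(a_rows[1], a_rows[2]), ang(a_rows[0], a_rows[2]), ang(a_rows[0], a_rows[1])
        )


@dataclass(frozen=True)
class PeakObservation:
    """A Bragg peak located on the detector (pixels) with an intensity."""

    x_px: float
    y_px: float
    intensity: float


@dataclass(frozen=True)
class UncertaintyLineSegment:
    """Radial reciprocal-space segment of possible RLP positions for one peak.

    ``direction`` is a unit vector; the segment is
    ``{t * direction : q_min <= t <= q_max}`` with ``q_min = |n - z| / lambda_max``
    and ``q_max = |n - z| / lambda_min``.
    """

    direction: np.ndarray
    q_min: float
    q_max: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not (0 < self.q_min <= self.q_max):
            raise ValueError("require 0 < q_min <= q_max")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("ULS direction must be a unit vector")
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.multiply.outer(np.asarray(t), self.direction)


@dataclass(frozen=True)
class ReciprocalLatticePoint:
    """A reciprocal-lattice point: Miller indices and unrotated position."""

    hkl: tuple[int, int, int]
    q0: np.ndarray


@dataclass
class RlpSet:
    """Vectorized container for a finite set of reciprocal-lattice points."""

    hkl: np.ndarray  # (n, 3) int
    q0: np.ndarray  # (n, 3) float
    norms: np.ndarray = field(default=None)  # (n,) float

    def __post_init__(self) -> None:
        if self.norms is None:
            self.norms = np.linalg.norm(self.q0, axis=1)

    def __len__(self) -> int:
        return len(self.hkl)

    def __iter__(self):
        for hkl, q0 in zip(self.hkl, self.q0):
            yield ReciprocalLatticePoint(tuple(int(v) for v in hkl), q0)

    def subset(self, mask: np.ndarray) -> "RlpSet":
        return RlpSet(self.hkl[mask], self.q0[mask], self.norms[mask])


def cell_to_reciprocal_basis(cell: UnitCell) -> ReciprocalBasis:
    """Reciprocal basis of a unit cell in its canonical lab-frame placement.

    The real-space basis is placed with ``a`` along ``+x`` and ``b`` in the
    ``xy`` plane; the reciprocal rows are the inverse transpose, so that
    ``B @ A.T = I`` holds to machine precision.
    """
    a_rows = cell.real_basis()
    return ReciprocalBasis(np.linalg.inv(a_rows.T))


def pixels_to_directions(xy_px: np.ndarray, geom: ExperimentGeometry) -> np.ndarray:
    """Unit scattering directions (n, 3) for detector positions (n, 2) in pixels."""
    xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
    dx = (xy[:, 0] - geom.beam_center_px[0]) * geom.pixel_size_mm
    dy = (xy[:, 1] - geom.beam_center_px[1]) * geom.pixel_size_mm
    dz = np.full(len(xy), geom.detector_distance_mm)
    v = np.column_stack([dx, dy, dz])
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def pixel_to_direction(peak: PeakObservation, geom: ExperimentGeometry) -> np.ndarray:
    """Unit vector from the sample toward one detector pixel."""
    return pixels_to_directions([[peak.x_px, peak.y_px]], geom)[0]


def build_uls(
    direction: np.ndarray,
    band: WavelengthBand,
    eps: float = 1e-10,
) -> UncertaintyLineSegment:
    """Uncertainty line segment for a scattering direction and wavelength band.

    Raises
    ------
    DegeneratePeakError
        If the scattering direction coincides with the beam (zero momentum
        transfer; such a "peak" carries no lattice information).
    """
    n = np.asarray(direction, dtype=float)
    e = n - BEAM_DIRECTION
    norm_e = np.linalg.norm(e)
    if norm_e < eps:
        raise DegeneratePeakError("peak lies on the direct beam; ULS undefined")
    return UncertaintyLineSegment(
        direction=e / norm_e,
        q_min=norm_e / band.lambda_max_A,
        q_max=norm_e / band.lambda_min_A,
    )


def build_ulss(
    xy_px: np.ndarray, geom: ExperimentGeometry, band: WavelengthBand, eps: float = 1e-10
) -> tuple[list[UncertaintyLineSegment | None], np.ndarray]:
    """ULSs for many peaks at once.

    Returns a list aligned with the input rows (``None`` for degenerate peaks
    on the direct beam) and a boolean validity mask.
    """
    dirs = pixels_to_directions(xy_px, geom)
    out: list[UncertaintyLineSegment | None] = []
    valid = np.zeros(len(dirs), dtype=bool)
    for i, n in enumerate(dirs):
        try:
            out.append(build_uls(n, band, eps=eps))
            valid[i] = True
        except DegeneratePeakError:
            out.append(None)
    return out, valid


def generate_rlps(
    basis: ReciprocalBasis, q_cutoff: float, max_points: int = 2_000_000
) -> RlpSet:
    """All nonzero reciprocal-lattice points with ``|q| <= q_cutoff``.

    The result is deterministically ordered by ``|q|`` then lexicographically
    by ``(h, k, l)``.  Closed under Friedel negation by construction.

    Raises
    ------
    ResourceLimitError
        If the enumeration box would exceed ``max_points`` candidates.
    """
    if q_cutoff <= 0:
        raise ValueError("q_cutoff must be positive")
    a_rows = basis.real_rows()
    # |h_i| = |q . a_i| <= q_cutoff * |a_i|
    hmax = np.floor(q_cutoff * np.linalg.norm(a_rows, axis=1) + 1e-9).astype(int)
    n_box = np.prod(2 * hmax.astype(np.int64) + 1)
    if n_box > max_points:
        raise ResourceLimitError(
            f"RLP enumeration box holds {n_box} points (> max_points={max_points})"
        )
    ranges = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    q = H @ basis.rows
    norms = np.linalg.norm(q, axis=1)
    keep = (norms <= q_cutoff) & (norms > 0)
    H, q, norms = H[keep], q[keep], norms[keep]
    order = np.lexsort((H[:, 2], H[:, 1], H[:, 0], norms))
    return RlpSet(H[order], q[order], norms[order])


def candidate_rlps(
    uls: UncertaintyLineSegment, rlps: RlpSet, tolerance: float
) -> RlpSet:
    """RLPs whose norm falls inside the tolerance-widened ULS radial shell.

    A lattice rotation can bring an RLP onto the ULS exactly when its norm
    lies between the segment's radial bounds; the test is rotation invariant.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    lo = (1.0 - tolerance) * uls.q_min
    hi = (1.0 + tolerance) * uls.q_max
    return rlps.subset((rlps.norms >= lo) & (rlps.norms <= hi))


def wavelength_of_q(q: np.ndarray) -> np.ndarray:
    """Excitation wavelength implied by the elastic condition for each ``q``.

    ``lambda = -2 q_z / |q|^2``; positive only for ``q_z < 0`` (points below
    the plane through the reciprocal-space origin normal to the beam).
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    n2 = np.einsum("ij,ij->i", q, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = -2.0 * q[:, 2] / n2
    return lam
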