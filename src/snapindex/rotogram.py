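"""Rotogram: voxel accumulation of per-peak orientation curves.

Every candidate RLP of every observed peak defines a one-parameter family of
lattice rotations that place the candidate onto the peak's uncertainty line
segment.  Embedded into the bounded rotation ball, each family traces a closed
planar curve.  Rasterizing all curves of one peak into a binary voxel grid,
dilating by the 26-neighborhood, and summing the per-peak grids yields the
*rotogram*: each voxel counts how many peaks are predicted by the orientation
at its center.  The maximum voxel is the coarse indexing solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoCandidatesError, NoSolutionError
from .geometry import UncertaintyLineSegment
from .rotations import R_BALL, Rotation, map_quats, unmap_rotation

__all__ = [
    "VoxelGrid",
    "ANGLE_RESOLUTION_PRESETS",
    "rotogram_curve",
    "curve_points",
    "accumulate_rotogram",
    "best_orientation",
    "tied_orientations",
]

#: Voxels per axis for the named angle-resolution presets (odd, so one voxel
#: is centered on the identity rotation).
ANGLE_RESOLUTION_PRESETS = {"loose": 45, "balanced": 71, "dense": 101}

#: Upper bound on the rotation-angle sampling step along each curve (radians).
MAX_PHI_STEP = 0.1

#: Chord subdivision target for accumulation, in voxel units.  The 26-neighbor
#: dilation bridges Chebyshev gaps of up to two voxels, so rasterizing at just
#: under two voxels per point keeps every dilated curve 26-connected while
#: halving the point load relative to strict one-voxel stepping.
RASTER_STEP_VOXELS = 1.8


@dataclass
class VoxelGrid:
    """Cubic voxel grid over the rotation ball ``[-r_ball, r_ball]^3``."""

    n: int
    values: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError("voxel count per axis must be odd and >= 3")
        if self.values is None:
            self.values = np.zeros((self.n, self.n, self.n), dtype=np.int32)
        elif self.values.shape != (self.n, self.n, self.n):
            raise ValueError("values shape does not match n")

    @property
    def voxel_size(self) -> float:
        return 2.0 * R_BALL / self.n

    def coords_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel coordinates (n, 3) of ball points (n, 3)."""
        c = np.floor((np.asarray(points) + R_BALL) / self.voxel_size).astype(np.int64)
        return np.clip(c, 0, self.n - 1)

    def center_of(self, coords: np.ndarray) -> np.ndarray:
        """Ball-space center of integer voxel coordinates."""
        return (np.asarray(coords) + 0.5) * self.voxel_size - R_BALL

    @property
    def angular_diagonal_deg(self) -> float:
        """Worst-case misorientation across one voxel diagonal, degrees.

        Bounded by the inverse embedding evaluated over a voxel diagonal at
        the coarsest part of the radial scale (near the ball surface the
        radial derivative d(theta)/dr = 6 r^2 is largest).
        """
        dr = np.sqrt(3.0) * self.voxel_size
        return float(np.degrees(6.0 * R_BALL**2 * dr))


def _base_phis() -> np.ndarray:
    k = int(np.ceil(2.0 * np.pi / MAX_PHI_STEP))
    return -np.pi + 2.0 * np.pi * np.arange(k) / k


def _densify_closed(points: np.ndarray, valid_seg: np.ndarray, step: float) -> np.ndarray:
    """Subdivide chords of closed curves so consecutive points sit in
    neighboring voxels.

    Parameters
    ----------
    points:
        (m, k, 3) sample points of m closed curves sharing a phi grid.
    valid_seg:
        (m, k) mask; segment i -> i+1 (cyclic) is drawn only where True.
        Segments crossing the ball surface (antipodal quaternion flips) are
        excluded: the curve genuinely exits and re-enters there.
    step:
        Maximum allowed Chebyshev distance between consecutive emitted points.
    """
    a = points.reshape(-1, 3)
    b = np.roll(points, -1, axis=1).reshape(-1, 3)
    mask = valid_seg.reshape(-1)
    a_s, b_s = a[mask], b[mask]
    if len(a_s) == 0:
        return a
    d = b_s - a_s
    cheb = np.max(np.abs(d), axis=1)
    k = np.maximum(np.ceil(cheb / step).astype(np.int64), 1)
    need = k > 1
    if not np.any(need):
        return a
    a_n, d_n, k_n = a_s[need], d[need], k[need]
    n_interior = k_n - 1
    total = int(n_interior.sum())
    seg_id = np.repeat(np.arange(len(k_n)), n_interior)
    starts = np.concatenate([[0], np.cumsum(n_interior)[:-1]])
    within = np.arange(total) - np.repeat(starts, n_interior) + 1
    t = within / np.repeat(k_n, n_interior)
    interior = a_n[seg_id] + t[:, None] * d_n[seg_id]
    return np.vstack([a, interior])


def curve_points(
    q0: np.ndarray, uls: UncertaintyLineSegment, grid: VoxelGrid
) -> np.ndarray:
    """Rotogram-ball points of the orientation curve for one candidate RLP.

    The rotation-angle parameter is sampled at steps of at most 0.1 rad over
    one full turn, then every chord is subdivided until consecutive points
    fall in the same or 26-adjacent voxels, so rasterization cannot skip
    voxels.
    """
    return _all_curve_points(
        np.atleast_2d(np.asarray(q0, dtype=float)), uls, grid, step_voxels=0.9
    )


def rotogram_curve(
    q0: np.ndarray, uls: UncertaintyLineSegment, grid: VoxelGrid
) -> np.ndarray:
    """Alias of :func:`curve_points` (returns the sampled ball points)."""
    return curve_points(q0, uls, grid)


def _all_curve_points(
    q0s: np.ndarray,
    uls: UncertaintyLineSegment,
    grid: VoxelGrid,
    step_voxels: float = RASTER_STEP_VOXELS,
) -> np.ndarray:
    """Dense ball points of the curves of all candidates of one peak."""
    phis = _base_phis()
    p_hats = q0s / np.linalg.norm(q0s, axis=1, keepdims=True)
    s = p_hats + uls.direction[None, :]
    ns = np.linalg.norm(s, axis=1)
    ok = ns > 1e-9  # drop antiparallel candidates (undefined bisector)
    if not np.any(ok):
        return np.empty((0, 3))
    m = s[ok] / ns[ok, None]
    d = uls.direction
    h = 0.5 * phis
    ch, sh = np.cos(h), np.sin(h)
    dm = m @ d  # (M,)
    dxm = np.cross(np.broadcast_to(d, m.shape), m)  # (M, 3)
    # q(phi) = (cos h, sin h * d) (x) (0, m), vectorized over candidates and phi
    w = -np.outer(dm, sh)  # (M, K)
    vec = m[:, None, :] * ch[None, :, None] + dxm[:, None, :] * sh[None, :, None]
    quats = np.concatenate([w[:, :, None], vec], axis=2)  # (M, K, 4)
    mk = quats.shape[0] * quats.shape[1]
    pts = map_quats(quats.reshape(mk, 4)).reshape(quats.shape[0], quats.shape[1], 3)
    sign = np.where(w >= 0, 1.0, -1.0)
    flips = sign * np.roll(sign, -1, axis=1) < 0
    jump = np.max(np.abs(pts - np.roll(pts, -1, axis=1)), axis=2) > R_BALL
    valid = ~(flips & jump)
    return _densify_closed(pts, valid, step_voxels * grid.voxel_size)


def accumulate_rotogram(
    per_peak_candidates: list[tuple[UncertaintyLineSegment, np.ndarray]],
    grid_spec: int,
) -> VoxelGrid:
    """Sum of dilated per-peak binary rotograms.

    Parameters
    ----------
    per_peak_candidates:
        One entry per considered peak: its ULS and the (m, 3) array of
        candidate RLP positions ``q0`` (unrotated basis).
    grid_spec:
        Odd voxel count per axis.

    Each peak contributes a *binary* grid (all its curves rasterized, then
    dilated by the full 26-neighborhood), so a peak with many candidates still
    adds at most 1 to any voxel; the sum counts predicted peaks per voxel.
    """
    grid = VoxelGrid(grid_spec)
    n = grid.n
    n_pad = n + 2
    flags = np.zeros((n_pad, n_pad, n_pad), dtype=bool)
    dilated = np.zeros_like(flags)
    contributed = 0
    for uls, q0s in per_peak_candidates:
        q0s = np.atleast_2d(np.asarray(q0s, dtype=float))
        if q0s.size == 0:
            continue
        pts = _all_curve_points(q0s, uls, grid)
        if len(pts) == 0:
            continue
        coords = grid.coords_of(pts) + 1  # into padded frame
        flat = (coords[:, 0] * n_pad + coords[:, 1]) * n_pad + coords[:, 2]
        flags.reshape(-1)[:] = False
        flags.reshape(-1)[flat] = True
        # 26-neighbor dilation as 27 shifted ORs at grid level
        dilated[:] = False
        core = flags[1 : n + 1, 1 : n + 1, 1 : n + 1]
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    dilated[
                        1 + dx : n + 1 + dx, 1 + dy : n + 1 + dy, 1 + dz : n + 1 + dz
                    ] |= core
        grid.values += dilated[1 : n + 1, 1 : n + 1, 1 : n + 1]
        contributed += 1
    if contributed == 0:
        raise NoCandidatesError("no peak has any candidate RLP")
    return grid


def tied_orientations(grid: VoxelGrid) -> list[tuple[Rotation, int, int]]:
    """All argmax voxels of the rotogram, ordered by flat voxel index.

    Returns tuples ``(rotation at voxel center, support, flat index)``.
    """
    vmax = int(grid.values.max())
    if vmax == 0:
        raise NoSolutionError("rotogram is empty (all-zero grid)")
    flat = np.flatnonzero(grid.values.reshape(-1) == vmax)
    out = []
    for f in flat:
        coords = np.unravel_index(f, grid.values.shape)
        v = grid.center_of(np.array(coords))
        r = np.linalg.norm(v)
        if r > R_BALL:  # corner voxels outside the ball: clamp onto surface
            v = v * (R_BALL / r)
        out.append((unmap_rotation(v), vmax, int(f)))
    return out


def best_orientation(grid: VoxelGrid) -> tuple[Rotation, int]:
    """Rotation at the center of the (first) maximum voxel and its support."""
    rot, support, _ = tied_orientations(grid)[0]
    return rot, support
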