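"""Rotations, the bounded rotogram embedding, and misorientation metrics.

Rotations are represented by unit quaternions ``(w, x, y, z)`` with ``w >= 0``
(the canonical representative of the double cover), equivalent to axis-angle
with angle in ``[0, pi]``.

The rotogram embedding maps a rotation with axis ``e`` and angle ``theta`` to
the point ``v = e * f(theta)`` with the nonlinear radial scale
``f(theta) = (theta / 2) ** (1/3)``.  The cube root spreads small-angle
rotations over more volume than plain axis-angle, giving a more uniform fill
of the ball of radius ``r_ball = f(pi)``; it is strictly increasing with
``f(0) = 0``, so the embedding is a bijection from rotation space onto the
ball (up to the antipodal identification on the surface, theta = pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from .errors import UndefinedBisectorError
from .geometry import UnitCell

__all__ = [
    "Rotation",
    "R_BALL",
    "embedding_radius",
    "embedding_angle",
    "map_rotation",
    "unmap_rotation",
    "map_quats",
    "reflection_rotation",
    "reflection_quats",
    "misorientation",
    "lattice_symmetry_rotations",
    "orientation_of_basis",
    "random_rotation",
]


def _canonical_quat(q: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so w >= 0; on w == 0, first nonzero component > 0."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    sign = np.sign(q[:, 0])
    for j in (1, 2, 3):  # resolve w == 0 ties deterministically
        sign = np.where(sign == 0, np.sign(q[:, j]), sign)
    sign = np.where(sign == 0, 1.0, sign)
    return q * sign[:, None]


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product, w-first, broadcasting over leading axes."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, v1 = q1[..., :1], q1[..., 1:]
    w2, v2 = q2[..., :1], q2[..., 1:]
    w = w1 * w2 - np.sum(v1 * v2, axis=-1, keepdims=True)
    v = w1 * v2 + w2 * v1 + np.cross(v1, v2)
    return np.concatenate([w, v], axis=-1)


@dataclass(frozen=True)
class Rotation:
    """A proper 3D rotation with canonical unit-quaternion storage."""

    quat: np.ndarray  # (4,) w-first, unit norm, w >= 0

    def __post_init__(self) -> None:
        q = np.asarray(self.quat, dtype=float).reshape(4)
        q = q / np.linalg.norm(q)
        object.__setattr__(self, "quat", _canonical_quat(q)[0])

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_axis_angle(cls, axis: np.ndarray, angle: float) -> "Rotation":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        h = 0.5 * angle
        return cls(np.concatenate([[np.cos(h)], np.sin(h) * axis]))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray) -> "Rotation":
        return cls(_scipy_to_wfirst(ScipyRotation.from_rotvec(rotvec)))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "Rotation":
        return cls(_scipy_to_wfirst(ScipyRotation.from_matrix(matrix)))

    # -- views -------------------------------------------------------------
    @property
    def angle(self) -> float:
        """Rotation angle in radians, in [0, pi]."""
        return float(2.0 * np.arccos(np.clip(self.quat[0], -1.0, 1.0)))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis; +z for the identity by convention."""
        v = self.quat[1:]
        n = np.linalg.norm(v)
        if n < 1e-300:
            return np.array([0.0, 0.0, 1.0])
        return v / n

    def as_matrix(self) -> np.ndarray:
        return _wfirst_to_scipy(self.quat).as_matrix()

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return _wfirst_to_scipy(self.quat).apply(vectors)

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "Rotation") -> "Rotation":
        """``self`` after ``other`` (matrix product self @ other)."""
        return Rotation(quat_multiply(self.quat, other.quat))

    def __matmul__(self, other: "Rotation") -> "Rotation":
        return self.compose(other)

    def inverse(self) -> "Rotation":
        w, x, y, z = self.quat
        return Rotation(np.array([w, -x, -y, -z]))

    def angle_to(self, other: "Rotation") -> float:
        """Geodesic angle (radians) between two rotations.

        Computed from the quaternion chord (stable near zero, where the
        arccos of the dot product loses half the floating-point digits).
        """
        chord = min(
            float(np.linalg.norm(self.quat - other.quat)),
            float(np.linalg.norm(self.quat + other.quat)),
        )
        return float(4.0 * np.arcsin(min(chord / 2.0, 1.0)))


def _scipy_to_wfirst(r: ScipyRotation) -> np.ndarray:
    q = r.as_quat()  # x, y, z, w
    return np.concatenate([q[..., 3:4], q[..., 0:3]], axis=-1)


def _wfirst_to_scipy(q: np.ndarray) -> ScipyRotation:
    q = np.asarray(q)
    return ScipyRotation.from_quat(np.concatenate([q[..., 1:4], q[..., 0:1]], axis=-1))


# ---------------------------------------------------------------------------
# Bounded nonlinear embedding of rotation space ("rotogram ball")
# ---------------------------------------------------------------------------

def embedding_radius(theta: np.ndarray) -> np.ndarray:
    """Radial scale ``f(theta) = (theta / 2) ** (1/3)``."""
    return np.cbrt(np.asarray(theta, dtype=float) / 2.0)


def embedding_angle(radius: np.ndarray) -> np.ndarray:
    """Inverse radial scale: ``theta = 2 * r**3``."""
    r = np.asarray(radius, dtype=float)
    return 2.0 * r * r * r


#: Radius of the embedding ball: the image of a half-turn rotation.
R_BALL = float(embedding_radius(np.pi))


def map_rotation(r: Rotation) -> np.ndarray:
    """Embed a rotation into the rotogram ball: ``v = axis * f(angle)``."""
    return map_quats(r.quat[None, :])[0]


def map_quats(quats: np.ndarray) -> np.ndarray:
    """Vectorized embedding of canonical quaternions (n, 4) -> points (n, 3)."""
    q = _canonical_quat(quats)
    # atan2 keeps full precision for small angles, unlike arccos(w)
    vn_ = np.linalg.norm(q[:, 1:], axis=1)
    theta = 2.0 * np.arctan2(vn_, q[:, 0])
    vn = np.linalg.norm(q[:, 1:], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(vn[:, None] > 1e-300, q[:, 1:] / np.maximum(vn, 1e-300)[:, None], 0.0)
    return axis * embedding_radius(theta)[:, None]


def unmap_rotation(v: np.ndarray) -> Rotation:
    """Inverse embedding: a ball point back to the rotation it encodes."""
    v = np.asarray(v, dtype=float)
    r = np.linalg.norm(v)
    if r < 1e-300:
        return Rotation.identity()
    if r > R_BALL * (1.0 + 1e-9):
        raise ValueError("point lies outside the rotation ball")
    theta = min(float(embedding_angle(r)), np.pi)
    return Rotation.from_axis_angle(v / r, theta)


# ---------------------------------------------------------------------------
# The per-peak rotation family
# ---------------------------------------------------------------------------

def reflection_rotation(p_hat: np.ndarray, d_hat: np.ndarray, phi: float) -> Rotation:
    """One member of the rotation family carrying direction ``p_hat`` to ``d_hat``.

    The family is ``R(phi) = R_d(phi) o R_m(pi)`` where ``m`` bisects ``p_hat``
    and ``d_hat``: the half-turn about the bisector maps ``p_hat`` exactly onto
    ``d_hat``, and the subsequent rotation about ``d_hat`` leaves it fixed, so
    ``R(phi) p_hat = d_hat`` for every ``phi``.  Composition is performed with
    quaternion (Rodrigues) multiplication.
    """
    return Rotation(reflection_quats(p_hat, d_hat, np.atleast_1d(float(phi)))[0])


def reflection_quats(
    p_hat: np.ndarray, d_hat: np.ndarray, phis: np.ndarray
) -> np.ndarray:
    """Quaternions (k, 4) of the family ``R_d(phi) o R_m(pi)`` over ``phis``.

    Raises
    ------
    UndefinedBisectorError
        If ``p_hat`` and ``d_hat`` are antiparallel (bisector undefined).
    """
    p = np.asarray(p_hat, dtype=float)
    d = np.asarray(d_hat, dtype=float)
    s = p + d
    ns = np.linalg.norm(s)
    if ns < 1e-9:
        raise UndefinedBisectorError("candidate and ULS directions are antiparallel")
    m = s / ns
    phis = np.asarray(phis, dtype=float)
    h = 0.5 * phis[:, None]
    # q2(phi) = (cos h, sin h * d); q1 = (0, m); q = q2 (x) q1
    ch, sh = np.cos(h), np.sin(h)
    w = -sh * (d @ m)
    vec = ch * m[None, :] + sh * np.cross(d, m)[None, :]
    return np.concatenate([w, vec], axis=1)


# ---------------------------------------------------------------------------
# Misorientation and lattice symmetry
# ---------------------------------------------------------------------------

def misorientation(
    r1: Rotation, r2: Rotation, symmetry_ops: list[Rotation] | None = None
) -> float:
    """Minimal angle (degrees) between two lattice orientations.

    Lattice orientations are equivalent up to the point-group rotations ``S``
    of the lattice acting in the reference (unrotated) frame:
    ``R ~ R o S``.  The misorientation is the minimum over the supplied ops of
    the geodesic angle between ``r1 o S`` and ``r2``.  With no ops (or just
    the identity) this is the plain rotation distance.
    """
    if symmetry_ops is None:
        symmetry_ops = [Rotation.identity()]
    best = np.inf
    for s in symmetry_ops:
        ang = (r1 @ s).angle_to(r2)
        if ang < best:
            best = ang
    return float(np.degrees(best))


def _closure(generators: list[np.ndarray]) -> list[np.ndarray]:
    """Finite group closure of rotation matrices (tolerant matching)."""
    ops: list[np.ndarray] = [np.eye(3)]

    def known(m):
        return any(np.allclose(m, o, atol=1e-9) for o in ops)

    frontier = [g for g in generators]
    while frontier:
        g = frontier.pop()
        if known(g):
            continue
        ops.append(g)
        for o in list(ops):
            for prod in (g @ o, o @ g):
                if not known(prod):
                    frontier.append(prod)
    return ops


def lattice_symmetry_rotations(cell: UnitCell, atol: float = 1e-6) -> list[Rotation]:
    """Proper point-group rotations of the lattice in its canonical placement.

    The lattice system is detected from the cell parameters (lengths/angles
    equal within ``atol``).  Supported: cubic (24 ops), tetragonal and
    hexagonal (axis along z), orthorhombic, monoclinic (unique axis b,
    canonical y), triclinic.  Rhombohedral and base-centred specialisations
    are treated as the lower-symmetry system they parameterize.
    """

    def eq(x, y):
        return abs(x - y) <= atol * max(1.0, abs(x), abs(y))

    right = eq(cell.alpha, 90) and eq(cell.beta, 90) and eq(cell.gamma, 90)
    rot = Rotation.from_axis_angle

    if right and eq(cell.a, cell.b) and eq(cell.b, cell.c):
        gens = [rot([0, 0, 1], np.pi / 2).as_matrix(), rot([1, 0, 0], np.pi / 2).as_matrix()]
    elif right and eq(cell.a, cell.b):
        # tetragonal: 4-fold along c. Canonical placement puts c along z.
        gens = [rot([0, 0, 1], np.pi / 2).as_matrix(), rot([1, 0, 0], np.pi).as_matrix()]
    elif eq(cell.alpha, 90) and eq(cell.beta, 90) and eq(cell.gamma, 120) and eq(cell.a, cell.b):
        gens = [rot([0, 0, 1], np.pi / 3).as_matrix(), rot([1, 0, 0], np.pi).as_matrix()]
    elif right:
        gens = [rot([0, 0, 1], np.pi).as_matrix(), rot([1, 0, 0], np.pi).as_matrix()]
    elif eq(cell.alpha, 90) and eq(cell.gamma, 90):
        gens = [rot([0, 1, 0], np.pi).as_matrix()]  # monoclinic, unique axis b
    else:
        gens = []
    return [Rotation.from_matrix(m) for m in _closure(gens)]


def orientation_of_basis(basis_rows: np.ndarray, reference_rows: np.ndarray) -> Rotation:
    """Rotation carrying a reference reciprocal basis onto an oriented one.

    Solves ``B = B0 @ R.T`` for the closest proper rotation ``R`` (orthogonal
    Procrustes), exact when the two bases differ by a pure rotation.
    """
    x = np.linalg.inv(np.asarray(reference_rows)) @ np.asarray(basis_rows)
    u, _, vt = np.linalg.svd(x)
    rt = u @ vt
    if np.linalg.det(rt) < 0:
        u[:, -1] *= -1
        rt = u @ vt
    return Rotation.from_matrix(rt.T)


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform random rotation (Haar measure) from a seeded generator."""
    q = rng.standard_normal(4)
    return Rotation(q)
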