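"""Solution refinement and scoring.

The coarse orientation from the rotogram is polished by minimizing the mean
Euclidean distance between each peak's uncertainty line segment and its
nearest reciprocal-lattice point, using finite-difference gradient descent
with backtracking.  Only inlier peaks (distance within a relative tolerance
of the assigned RLP's norm) enter the objective; the inlier set is re-selected
after every accepted step.

Two refinement modes exist: ``fixedLatticeParameters`` perturbs the basis by a
pure rotation (the six cell parameters are preserved exactly), while
``fitAllLatticeParameters`` refines all nine basis components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from .errors import InsufficientInliersError
from .geometry import ReciprocalBasis, UncertaintyLineSegment

__all__ = [
    "RefinementConfig",
    "PeakAssignment",
    "point_segment_distance",
    "assign_nearest_rlps",
    "score_solution",
    "refine_solution",
]

REFINEMENT_TYPES = ("fixedLatticeParameters", "fitAllLatticeParameters", "none")

#: Number of wavelengths sampled along each ULS when seeding the hkl search.
N_LAMBDA_SAMPLES = 16

_HKL_OFFSETS = np.stack(
    np.meshgrid(*([np.array([-1, 0, 1])] * 3), indexing="ij"), axis=-1
).reshape(-1, 3)


@dataclass(frozen=True)
class RefinementConfig:
    """Controls for the gradient-descent refinement."""

    refinement_type: str = "fixedLatticeParameters"
    max_iterations: int = 200
    convergence_tol: float = 1e-7
    finite_difference_step: float = 1e-6

    def __post_init__(self) -> None:
        if self.refinement_type not in REFINEMENT_TYPES:
            raise ValueError(f"refinement_type must be one of {REFINEMENT_TYPES}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PeakAssignment:
    """Per-peak nearest-RLP assignment for a list of ULSs."""

    hkl: np.ndarray  # (p, 3) int
    distance: np.ndarray  # (p,) 1/Angstrom
    inlier: np.ndarray  # (p,) bool

    @property
    def n_inliers(self) -> int:
        return int(self.inlier.sum())


def point_segment_distance(q: np.ndarray, uls: UncertaintyLineSegment) -> float:
    """Euclidean distance from a point to the closed ULS segment."""
    q = np.asarray(q, dtype=float)
    t = float(np.clip(q @ uls.direction, uls.q_min, uls.q_max))
    return float(np.linalg.norm(q - t * uls.direction))


def _uls_arrays(
    ulss: list[UncertaintyLineSegment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dirs = np.array([u.direction for u in ulss])
    qmin = np.array([u.q_min for u in ulss])
    qmax = np.array([u.q_max for u in ulss])
    return dirs, qmin, qmax


def assign_nearest_rlps(
    basis: ReciprocalBasis,
    ulss: list[UncertaintyLineSegment],
    tolerance: float,
) -> PeakAssignment:
    """Nearest reciprocal-lattice point to each ULS, with inlier flags.

    The search seeds Miller indices by inverting the basis at
    ``N_LAMBDA_SAMPLES`` radial positions along each segment and expanding the
    rounded triples by +-1 in each index — a bounded window that is complete
    whenever the tolerance is small compared with the shortest reciprocal
    vector.  A peak is an inlier iff its distance is at most
    ``tolerance * |q_rlp|``.
    """
    if len(ulss) == 0:
        return PeakAssignment(
            np.zeros((0, 3), dtype=int), np.zeros(0), np.zeros(0, dtype=bool)
        )
    dirs, qmin, qmax = _uls_arrays(ulss)
    p = len(ulss)
    ts = qmin[:, None] + (qmax - qmin)[:, None] * np.linspace(0.0, 1.0, N_LAMBDA_SAMPLES)
    targets = dirs[:, None, :] * ts[:, :, None]  # (p, s, 3)
    binv = np.linalg.inv(basis.rows)
    hkl_f = targets @ binv  # (p, s, 3)
    base = np.round(hkl_f).astype(np.int64)
    cand = base[:, :, None, :] + _HKL_OFFSETS[None, None, :, :]  # (p, s, 27, 3)
    cand = cand.reshape(p, -1, 3)
    q = cand.astype(float) @ basis.rows  # (p, m, 3)
    t = np.clip(np.einsum("pmj,pj->pm", q, dirs), qmin[:, None], qmax[:, None])
    resid = q - t[:, :, None] * dirs[:, None, :]
    dist = np.linalg.norm(resid, axis=2)
    dist[np.all(cand == 0, axis=2)] = np.inf  # exclude the origin
    best = np.argmin(dist, axis=1)
    rows = np.arange(p)
    hkl_best = cand[rows, best]
    dist_best = dist[rows, best]
    qn = np.linalg.norm(hkl_best.astype(float) @ basis.rows, axis=1)
    inlier = dist_best <= tolerance * qn
    return PeakAssignment(hkl_best, dist_best, inlier)


def score_solution(
    basis: ReciprocalBasis, ulss: list[UncertaintyLineSegment], tolerance: float
) -> int:
    """Number of peaks fitted (inliers) by a basis at the given tolerance."""
    return assign_nearest_rlps(basis, ulss, tolerance).n_inliers


def _objective(
    basis_rows: np.ndarray,
    hkl: np.ndarray,
    dirs: np.ndarray,
    qmin: np.ndarray,
    qmax: np.ndarray,
) -> float:
    """Mean segment distance of a fixed hkl assignment under a basis."""
    q = hkl.astype(float) @ basis_rows
    t = np.clip(np.einsum("pj,pj->p", q, dirs), qmin, qmax)
    return float(np.mean(np.linalg.norm(q - t[:, None] * dirs, axis=1)))


def refine_solution(
    basis: ReciprocalBasis,
    ulss: list[UncertaintyLineSegment],
    config: RefinementConfig,
    tolerance: float,
) -> ReciprocalBasis:
    """Refine a basis against the ULSs by gradient descent.

    The objective is the mean distance from each current inlier's assigned RLP
    to its segment.  Steps are accepted only if they decrease the objective
    (monotone by construction); after each accepted step the nearest-RLP
    assignment and the inlier set are recomputed.  Outliers never enter the
    objective, so spurious peaks cannot drag the solution.

    Raises
    ------
    InsufficientInliersError
        If fewer than three peaks are inliers at the starting basis.
    """
    if config.refinement_type == "none":
        return basis
    fit_all = config.refinement_type == "fitAllLatticeParameters"

    dirs_all, qmin_all, qmax_all = _uls_arrays(ulss)
    rows0 = basis.rows.copy()

    assignment = assign_nearest_rlps(basis, ulss, tolerance)
    if assignment.n_inliers < 3:
        raise InsufficientInliersError(
            f"only {assignment.n_inliers} inlier peaks; need >= 3"
        )

    rows = rows0
    scale = float(np.mean(np.abs(rows)))
    step0 = 2e-3 if not fit_all else 2e-3 * scale
    fd = config.finite_difference_step * (1.0 if not fit_all else scale)
    n_params = 9 if fit_all else 3

    def apply_params(rows_cur: np.ndarray, x: np.ndarray) -> np.ndarray:
        if fit_all:
            return rows_cur + x.reshape(3, 3)
        rot = ScipyRotation.from_rotvec(x).as_matrix()
        return rows_cur @ rot.T

    step_cur = step0
    step_max = (0.05 if not fit_all else 0.05 * scale)
    prev_obj = None
    for _ in range(config.max_iterations):
        mask = assignment.inlier
        hkl = assignment.hkl[mask]
        dirs, qmin, qmax = dirs_all[mask], qmin_all[mask], qmax_all[mask]

        def f(x: np.ndarray) -> float:
            return _objective(apply_params(rows, x), hkl, dirs, qmin, qmax)

        x0 = np.zeros(n_params)
        f0 = f(x0)
        grad = np.empty(n_params)
        for j in range(n_params):
            xj = x0.copy()
            xj[j] += fd
            grad[j] = (f(xj) - f0) / fd
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-300:
            break
        direction = -grad / gnorm
        step = step_cur
        accepted = False
        for halving in range(20):
            fx = f(direction * step)
            if fx < f0:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        # grow the trial step after an immediate acceptance, shrink otherwise
        step_cur = min(step * 2.0, step_max) if halving == 0 else step
        rows = apply_params(rows, direction * step)
        assignment = assign_nearest_rlps(ReciprocalBasis(rows), ulss, tolerance)
        if assignment.n_inliers < 3:
            # step destroyed the inlier set; keep the previous basis
            rows = apply_params(rows, -direction * step)
            break
        if prev_obj is not None and prev_obj > 0:
            if abs(prev_obj - fx) / prev_obj < config.convergence_tol:
                prev_obj = fx
                break
        prev_obj = fx

    return ReciprocalBasis(rows)
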