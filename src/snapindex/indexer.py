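"""End-to-end indexing of a snapshot diffraction pattern.

Pipeline: select the strongest peaks, build their uncertainty line segments,
enumerate candidate reciprocal-lattice points for the known cell, accumulate
the rotogram, take the maximum-support orientation(s), refine, assign Miller
indices and excitation wavelengths to every peak, and accept the solution if
enough peaks are fitted.  Multi-crystal patterns are handled by indexing
iteratively and removing each accepted solution's inlier peaks.

Monochromatic, pink-beam and electron diffraction all run through the same
code path: the monochromatic case is simply the zero-bandwidth limit in which
every ULS degenerates to a point, and the electron case is the small-lambda
limit in which the Ewald sphere is nearly flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientInliersError,
    InsufficientPeaksError,
    NoCandidatesError,
    NoSolutionError,
)
from .geometry import (
    ExperimentGeometry,
    ReciprocalBasis,
    UncertaintyLineSegment,
    UnitCell,
    WavelengthBand,
    build_ulss,
    candidate_rlps,
    cell_to_reciprocal_basis,
    generate_rlps,
    wavelength_of_q,
)
from .refine import (
    RefinementConfig,
    assign_nearest_rlps,
    refine_solution,
)
from scipy.spatial.transform import Rotation as ScipyRotation

from .rotations import R_BALL, Rotation, orientation_of_basis
from .rotogram import ANGLE_RESOLUTION_PRESETS, VoxelGrid, accumulate_rotogram

__all__ = [
    "IndexerParams",
    "IndexingSolution",
    "index_pattern",
    "index_multi",
    "predict_reflections",
    "assign_wavelengths",
]


@dataclass(frozen=True)
class IndexerParams:
    """User-facing indexing parameters.

    Attributes
    ----------
    tolerance:
        Relative distance threshold deciding when a peak is correctly fitted
        (fraction of the assigned RLP's norm).
    considered_peaks_count:
        Number of strongest peaks used to build the rotogram; all peaks are
        used during refinement and scoring.
    angle_resolution:
        Rotogram resolution preset: ``loose`` (45 voxels per axis),
        ``balanced`` (71) or ``dense`` (101).
    refinement_type:
        ``fixedLatticeParameters``, ``fitAllLatticeParameters`` or ``none``.
    max_lattices:
        Upper bound on crystals sought per pattern (``index_multi``).
    min_fitted_fraction:
        A solution is accepted only if it fits at least this fraction of the
        (non-degenerate) peaks.
    min_peaks:
        Minimum number of peaks required to attempt indexing.
    q_cutoff:
        Optional reciprocal-space radius for RLP enumeration; by default the
        tolerance-widened maximum ULS radius over the considered peaks.
    max_rlps:
        Resource limit passed to the lattice enumeration.
    max_refined_ties:
        At most this many tied rotogram maxima are refined and compared.
    core_bandwidth:
        Optional relative full width of a sub-band, centred on the nominal
        wavelength, used *only* to build the uncertainty line segments for
        the rotogram stage.  For spectra with long faint tails the full band
        makes the candidate shells so wide that the rotogram loses contrast;
        restricting the voting stage to the spectral core (e.g. the FWHM)
        keeps it sharp, because only a majority of peaks needs to vote for
        the true orientation.  Refinement, scoring and wavelength assignment
        always use the full band.  ``None`` uses the full band throughout.
    """

    tolerance: float = 0.02
    considered_peaks_count: int = 30
    angle_resolution: str = "balanced"
    refinement_type: str = "fixedLatticeParameters"
    max_lattices: int = 1
    min_fitted_fraction: float = 0.25
    min_peaks: int = 5
    q_cutoff: float | None = None
    max_rlps: int = 2_000_000
    max_refined_ties: int = 10
    core_bandwidth: float | None = None
    #: safety cap on how many tied rotogram maxima are pre-scored
    max_prescored_ties: int = 16384
    #: explicit voxel count per axis, overriding the named preset; useful for
    #: wide-bandwidth patterns whose high candidate multiplicity demands a
    #: finer grid to keep the rotogram from saturating
    grid_n_override: int | None = None
    #: voting workload limits.  Peaks are admitted to the rotogram in order
    #: of increasing candidate multiplicity, subject to a per-peak
    #: multiplicity cap (a peak with thousands of candidate RLPs paints so
    #: many curves that its binary grid covers most of the ball and carries
    #: almost no information) and a total curve budget; at least
    #: ``min_vote_peaks`` always vote.  All peaks still enter refinement and
    #: scoring regardless.
    vote_curve_budget: int = 20000
    vote_multiplicity_cap: int = 600
    min_vote_peaks: int = 8

    def __post_init__(self) -> None:
        if self.min_peaks < 5:
            raise ValueError("min_peaks must be >= 5")
        if self.considered_peaks_count < self.min_peaks:
            raise ValueError("considered_peaks_count must be >= min_peaks")
        if not (0.0 < self.min_fitted_fraction <= 1.0):
            raise ValueError("min_fitted_fraction must lie in (0, 1]")
        if self.angle_resolution not in ANGLE_RESOLUTION_PRESETS:
            raise ValueError(
                f"angle_resolution must be one of {sorted(ANGLE_RESOLUTION_PRESETS)}"
            )

    @property
    def grid_n(self) -> int:
        if self.grid_n_override is not None:
            return self.grid_n_override
        return ANGLE_RESOLUTION_PRESETS[self.angle_resolution]

    def refinement_config(self) -> RefinementConfig:
        return RefinementConfig(refinement_type=self.refinement_type)


@dataclass
class IndexingSolution:
    """An oriented (optionally refined) lattice with per-peak bookkeeping.

    Per-peak arrays are aligned with the peak list given to the indexer
    (``peak_indices`` maps to the original pattern when peaks were removed by
    multi-lattice iteration).  Peaks whose ULS is degenerate, whose residual
    exceeds the tolerance, or whose fitted wavelength falls outside the
    tolerance-widened band are outliers: ``inlier`` False and wavelength NaN.
    """

    basis: ReciprocalBasis
    hkl: np.ndarray  # (n, 3) int
    wavelength: np.ndarray  # (n,) Angstrom, NaN for outliers
    residual: np.ndarray  # (n,) 1/Angstrom, inf for degenerate peaks
    inlier: np.ndarray  # (n,) bool
    score: int
    rotation: Rotation
    support: int  # rotogram votes at the chosen voxel
    peak_indices: np.ndarray = field(default=None)  # (n,) into the original pattern

    def __post_init__(self) -> None:
        if self.peak_indices is None:
            self.peak_indices = np.arange(len(self.hkl))

    @property
    def n_peaks(self) -> int:
        return len(self.hkl)


def _candidate_ties(
    grid: VoxelGrid, params: IndexerParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-slice voxels of the rotogram: (flat indices, supports, matrices).

    Discretization, symmetry replication and the doubled representation of
    near-half-turn rotations on the ball surface mean the true orientation
    can sit a vote or two below a spurious global maximum; the slice is
    therefore extended below the maximum level by level while it fits within
    ``max_prescored_ties``.  A maximum plateau larger than the budget
    (heavily saturated rotograms) is subsampled evenly by flat index.
    Rotation matrices of all voxel centers are built in one vectorized pass.
    """
    vmax = int(grid.values.max())
    if vmax == 0:
        raise NoSolutionError("rotogram is empty (all-zero grid)")
    values = grid.values.reshape(-1)
    flat = np.flatnonzero(values == vmax)
    if len(flat) > params.max_prescored_ties:
        sel = np.linspace(0, len(flat) - 1, params.max_prescored_ties).astype(int)
        flat = flat[np.unique(sel)]
    else:
        level = vmax
        floor = max(1, vmax - 2)
        while level - 1 >= floor:
            nxt = np.flatnonzero(values == level - 1)
            if len(flat) + len(nxt) > params.max_prescored_ties:
                break
            flat = np.concatenate([flat, nxt])
            level -= 1
    coords = np.stack(np.unravel_index(flat, grid.values.shape), axis=1)
    v = grid.center_of(coords)
    r = np.linalg.norm(v, axis=1)
    over = r > R_BALL
    v[over] *= (R_BALL / r[over])[:, None]
    r = np.minimum(r, R_BALL)
    theta = np.minimum(2.0 * r**3, np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        axes = np.where(r[:, None] > 1e-300, v / np.maximum(r, 1e-300)[:, None], 0.0)
    mats = ScipyRotation.from_rotvec(axes * theta[:, None]).as_matrix()
    return flat, values[flat], mats


def _prescore_ties(
    basis0: ReciprocalBasis,
    rot_mats: np.ndarray,
    ulss: list[UncertaintyLineSegment],
    tolerance: float,
    n_lambda: int = 8,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Inlier counts and mean residuals of many candidate orientations.

    Vectorized nearest-RLP assignment of every tie rotation (T, 3, 3) against
    a small set of ULSs, working in the unrotated lattice frame (the ULS
    directions are rotated instead of the basis).  Returns (inliers (T,),
    mean distance (T,)).
    """
    dirs = np.array([u.direction for u in ulss])
    qmin = np.array([u.q_min for u in ulss])
    qmax = np.array([u.q_max for u in ulss])
    p = len(ulss)
    binv = np.linalg.inv(basis0.rows)
    ts = qmin[:, None] + (qmax - qmin)[:, None] * np.linspace(0.0, 1.0, n_lambda)
    t_count = len(rot_mats)
    inliers = np.empty(t_count, dtype=np.int64)
    meandist = np.empty(t_count)
    for start in range(0, t_count, chunk):
        rots = rot_mats[start : start + chunk]  # (t, 3, 3)
        d_rot = np.einsum("pj,tji->tpi", dirs, rots)  # R^T d per tie
        targets = d_rot[:, :, None, :] * ts[None, :, :, None]  # (t, p, s, 3)
        hkl_f = targets @ binv
        base = np.round(hkl_f).astype(np.int64)
        cand = (base[:, :, :, None, :] + _HKL_OFFSETS_I64).reshape(
            len(rots), p, -1, 3
        )
        q = cand.astype(float) @ basis0.rows  # (t, p, m, 3)
        proj = np.einsum("tpmj,tpj->tpm", q, d_rot)
        proj = np.clip(proj, qmin[None, :, None], qmax[None, :, None])
        resid = q - proj[:, :, :, None] * d_rot[:, :, None, :]
        dist = np.linalg.norm(resid, axis=3)
        dist[np.all(cand == 0, axis=3)] = np.inf
        best = np.argmin(dist, axis=2)
        ti, pi = np.meshgrid(np.arange(len(rots)), np.arange(p), indexing="ij")
        dbest = dist[ti, pi, best]
        qn = np.linalg.norm(q[ti, pi, best], axis=2)
        inl = dbest <= tolerance * qn
        inliers[start : start + len(rots)] = inl.sum(axis=1)
        meandist[start : start + len(rots)] = dbest.mean(axis=1)
    return inliers, meandist


_HKL_OFFSETS_I64 = np.stack(
    np.meshgrid(*([np.array([-1, 0, 1])] * 3), indexing="ij"), axis=-1
).reshape(-1, 3)[None, None, None, :, :]


def _select_considered(intensities: np.ndarray, valid: np.ndarray, count: int) -> np.ndarray:
    """Indices of the top-``count`` valid peaks by intensity (stable order)."""
    idx = np.flatnonzero(valid)
    order = np.argsort(-intensities[idx], kind="stable")
    return idx[order[:count]]


def _solution_from_basis(
    basis: ReciprocalBasis,
    basis0: ReciprocalBasis,
    ulss: list[UncertaintyLineSegment | None],
    valid: np.ndarray,
    band: WavelengthBand,
    tolerance: float,
    support: int,
) -> IndexingSolution:
    n = len(ulss)
    hkl = np.zeros((n, 3), dtype=int)
    wavelength = np.full(n, np.nan)
    residual = np.full(n, np.inf)
    inlier = np.zeros(n, dtype=bool)
    valid_idx = np.flatnonzero(valid)
    assignment = assign_nearest_rlps(basis, [ulss[i] for i in valid_idx], tolerance)
    hkl[valid_idx] = assignment.hkl
    residual[valid_idx] = assignment.distance
    inlier[valid_idx] = assignment.inlier
    sol = IndexingSolution(
        basis=basis,
        hkl=hkl,
        wavelength=wavelength,
        residual=residual,
        inlier=inlier,
        score=0,
        rotation=orientation_of_basis(basis.rows, basis0.rows),
        support=support,
    )
    assign_wavelengths(sol, ulss, band, tolerance)
    return sol


def assign_wavelengths(
    solution: IndexingSolution,
    ulss: list[UncertaintyLineSegment | None],
    band: WavelengthBand,
    tolerance: float,
) -> np.ndarray:
    """Excitation wavelength of every inlier peak; demote out-of-band peaks.

    The wavelength follows from the elastic condition at the assigned rotated
    RLP, ``lambda = -2 q_z / |q|^2``.  Peaks whose wavelength falls outside
    the tolerance-widened band are demoted to outliers and the score is
    recomputed.  The widening accounts for the sensitivity of the implied
    wavelength to a positional offset within the distance tolerance: a
    displacement of ``tolerance * |q|`` along the beam shifts the implied
    wavelength by a relative ``2 * tolerance / (|q| * lambda)``, which
    dominates in the flat-Ewald-sphere (electron) limit where ``|q| * lambda``
    is small.  Updates ``solution`` in place and returns the wavelengths.
    """
    idx = np.flatnonzero(solution.inlier)
    solution.wavelength[:] = np.nan
    if len(idx):
        q = solution.basis.q_of_hkl(solution.hkl[idx])
        lam = wavelength_of_q(q)
        qn = np.linalg.norm(q, axis=1)
        tol_lam = tolerance * np.maximum(
            1.0, 2.0 / np.maximum(qn * band.lambda_nominal_A, 1e-300)
        )
        ok = (
            (lam > 0)
            & (lam >= band.lambda_min_A * (1.0 - tol_lam))
            & (lam <= band.lambda_max_A * (1.0 + tol_lam))
        )
        solution.wavelength[idx[ok]] = lam[ok]
        solution.inlier[idx[~ok]] = False
    solution.score = int(solution.inlier.sum())
    return solution.wavelength


def index_pattern(
    peaks: np.ndarray,
    geom: ExperimentGeometry,
    band: WavelengthBand,
    cell: UnitCell,
    params: IndexerParams = IndexerParams(),
) -> IndexingSolution:
    """Index a single-crystal snapshot pattern.

    Parameters
    ----------
    peaks:
        (n, 3) array of ``x_px, y_px, intensity`` rows (or an iterable of
        :class:`~snapindex.geometry.PeakObservation`).

    Raises
    ------
    InsufficientPeaksError
        If fewer than ``params.min_peaks`` peaks are supplied.
    NoSolutionError
        If no orientation fits at least ``min_fitted_fraction`` of the peaks.
    """
    peaks = _as_peak_array(peaks)
    if len(peaks) < params.min_peaks:
        raise InsufficientPeaksError(
            f"{len(peaks)} peaks supplied; need >= {params.min_peaks}"
        )
    basis0 = cell_to_reciprocal_basis(cell)
    ulss, valid = build_ulss(peaks[:, :2], geom, band)
    if valid.sum() < params.min_peaks:
        raise InsufficientPeaksError("too few non-degenerate peaks")

    considered = _select_considered(peaks[:, 2], valid, params.considered_peaks_count)

    # ULSs for the voting stage: optionally restricted to the spectral core
    if params.core_bandwidth is not None and not band.is_monochromatic:
        half = 0.5 * params.core_bandwidth * band.lambda_nominal_A
        core_band = WavelengthBand(
            max(band.lambda_min_A, band.lambda_nominal_A - half),
            min(band.lambda_max_A, band.lambda_nominal_A + half),
            band.lambda_nominal_A,
        )
        vote_ulss, _ = build_ulss(peaks[:, :2], geom, core_band)
    else:
        vote_ulss = ulss

    q_cutoff = params.q_cutoff
    if q_cutoff is None:
        q_cutoff = (1.0 + params.tolerance) * max(ulss[i].q_max for i in considered)
    rlps = generate_rlps(basis0, q_cutoff, max_points=params.max_rlps)

    per_peak_all: list[tuple[UncertaintyLineSegment, np.ndarray]] = []
    for i in considered:
        if vote_ulss[i] is None:
            continue
        cands = candidate_rlps(vote_ulss[i], rlps, params.tolerance)
        per_peak_all.append((vote_ulss[i], cands.q0))
    # admit peaks by increasing multiplicity under the per-peak cap and the
    # total curve budget
    order = np.argsort([len(q0s) for _, q0s in per_peak_all], kind="stable")
    per_peak, total = [], 0
    for j in order:
        uls_j, q0s_j = per_peak_all[j]
        if len(per_peak) >= params.min_vote_peaks and (
            len(q0s_j) > params.vote_multiplicity_cap
            or total + len(q0s_j) > params.vote_curve_budget
        ):
            break
        per_peak.append((uls_j, q0s_j))
        total += len(q0s_j)
    grid = accumulate_rotogram(per_peak, params.grid_n)

    # Dilation spreads each maximum over a plateau of neighboring voxels (and
    # lattice symmetry replicates it); rank the tied voxels by fitted-peak
    # count, then mean residual, over the considered peaks, and refine only
    # the best few.
    flats, supports, mats = _candidate_ties(grid, params)
    if len(flats) > params.max_refined_ties:
        vote_ulss_used = [u for u, _ in per_peak]
        # the pre-scoring tolerance is widened: a voxel center can sit up
        # to half a voxel diagonal from the orientation it stands for, which
        # at coarse grids exceeds the strict inlier basin
        inliers, meandist = _prescore_ties(
            basis0, mats, vote_ulss_used, 1.5 * params.tolerance
        )
        order = sorted(
            range(len(flats)), key=lambda i: (-inliers[i], meandist[i], flats[i])
        )
        keep = order[: params.max_refined_ties]
        flats, supports, mats = flats[keep], supports[keep], mats[keep]
    refine_cfg = params.refinement_config()
    best: IndexingSolution | None = None
    best_key = None
    for support, mat in zip(supports, mats):
        basis = basis0.rotated(mat)
        if params.refinement_type != "none":
            try:
                basis = refine_solution(
                    basis,
                    [u for u, v in zip(ulss, valid) if v],
                    refine_cfg,
                    params.tolerance,
                )
            except InsufficientInliersError:
                continue
        sol = _solution_from_basis(
            basis, basis0, ulss, valid, band, params.tolerance, int(support)
        )
        mean_res = (
            float(np.mean(sol.residual[sol.inlier])) if sol.score else np.inf
        )
        key = (-sol.score, mean_res)
        if best is None or key < best_key:
            best, best_key = sol, key
    if best is None:
        raise NoSolutionError("no rotogram maximum produced a refinable solution")
    if best.score < params.min_fitted_fraction * int(valid.sum()):
        raise NoSolutionError(
            f"best solution fits {best.score}/{int(valid.sum())} peaks, below the "
            f"acceptance fraction {params.min_fitted_fraction}"
        )
    return best


def index_multi(
    peaks: np.ndarray,
    geom: ExperimentGeometry,
    band: WavelengthBand,
    cell: UnitCell,
    params: IndexerParams = IndexerParams(),
) -> list[IndexingSolution]:
    """Index a pattern that may contain several crystals.

    Repeatedly indexes and removes the inlier peaks of each accepted solution
    until no further solution is found, too few peaks remain, or
    ``params.max_lattices`` is reached.  Solutions are ordered by score
    descending.  Errors from the first iteration propagate; later iterations
    terminate the loop silently.
    """
    peaks = _as_peak_array(peaks)
    if len(peaks) < params.min_peaks:
        raise InsufficientPeaksError(
            f"{len(peaks)} peaks supplied; need >= {params.min_peaks}"
        )
    remaining = np.arange(len(peaks))
    solutions: list[IndexingSolution] = []
    while len(remaining) >= params.min_peaks and len(solutions) < params.max_lattices:
        try:
            sol = index_pattern(peaks[remaining], geom, band, cell, params)
        except (NoSolutionError, NoCandidatesError, InsufficientPeaksError):
            if not solutions:
                raise
            break
        sol.peak_indices = remaining.copy()
        solutions.append(sol)
        remaining = remaining[~sol.inlier]
    solutions.sort(key=lambda s: -s.score)
    return solutions


def predict_reflections(
    basis: ReciprocalBasis | IndexingSolution,
    band: WavelengthBand,
    geom: ExperimentGeometry,
    q_cutoff: float,
    max_rlps: int = 2_000_000,
) -> dict[str, np.ndarray]:
    """All reflections an oriented lattice produces within the band.

    For each RLP ``q`` with ``|q| <= q_cutoff``, the excitation wavelength is
    ``lambda = -2 q_z / |q|^2`` (positive only for ``q_z < 0``); the
    reflection is emitted iff ``lambda`` lies in the band and the diffracted
    ray ``n = lambda q + z`` (a unit vector by construction) hits the
    detector.  Returns arrays ``hkl``, ``lambda_A``, ``x_px``, ``y_px``,
    ``q`` sorted by Miller indices.
    """
    if isinstance(basis, IndexingSolution):
        basis = basis.basis
    rlps = generate_rlps(basis, q_cutoff, max_points=max_rlps)
    lam = wavelength_of_q(rlps.q0)
    keep = (lam > 0) & (lam >= band.lambda_min_A) & (lam <= band.lambda_max_A)
    q = rlps.q0[keep]
    hkl = rlps.hkl[keep]
    lam = lam[keep]
    n = lam[:, None] * q
    n[:, 2] += 1.0
    fwd = n[:, 2] > 1e-9
    q, hkl, lam, n = q[fwd], hkl[fwd], lam[fwd], n[fwd]
    x_mm = n[:, 0] / n[:, 2] * geom.detector_distance_mm
    y_mm = n[:, 1] / n[:, 2] * geom.detector_distance_mm
    x_px = x_mm / geom.pixel_size_mm + geom.beam_center_px[0]
    y_px = y_mm / geom.pixel_size_mm + geom.beam_center_px[1]
    nx, ny = geom.detector_shape_px
    on_det = (x_px >= 0) & (x_px <= nx - 1) & (y_px >= 0) & (y_px <= ny - 1)
    order = np.lexsort(
        (hkl[on_det][:, 2], hkl[on_det][:, 1], hkl[on_det][:, 0])
    )
    return {
        "hkl": hkl[on_det][order],
        "lambda_A": lam[on_det][order],
        "x_px": x_px[on_det][order],
        "y_px": y_px[on_det][order],
        "q": q[on_det][order],
    }


def _as_peak_array(peaks) -> np.ndarray:
    """Coerce peak input (array or PeakObservation iterable) to (n, 3) float."""
    if isinstance(peaks, np.ndarray):
        arr = np.atleast_2d(np.asarray(peaks, dtype=float))
    else:
        arr = np.array(
            [[p.x_px, p.y_px, p.intensity] if hasattr(p, "x_px") else list(p) for p in peaks],
            dtype=float,
        ).reshape(-1, 3)
    if arr.shape[1] != 3:
        raise ValueError("peaks must have columns x_px, y_px, intensity")
    return arr
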