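"""Evaluation protocols on synthetic data.

Re-enacts the standard checks for snapshot indexers against simulated ground
truth: misorientation against the true orientation with a strict 3-degree
correctness criterion, success-rate sweeps versus the number of peaks made
available to the indexer (lowest-scattering-angle or random selection), and
recovery of a rotation series indexed frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EvaluationAlignmentError, SnapindexError
from .geometry import ExperimentGeometry, UnitCell
from .indexer import IndexerParams, IndexingSolution, index_pattern
from .rotations import Rotation, lattice_symmetry_rotations, misorientation
from .simulate import SimulatedPattern, SimulationConfig, simulate_pattern

__all__ = [
    "EvaluationReport",
    "evaluate_indexing",
    "select_peaks",
    "make_reduced_pattern",
    "run_sweep",
    "series_angles",
]

#: Strict correctness threshold (degrees): a solution is correct iff its
#: misorientation is strictly below this.
CORRECT_THRESHOLD_DEG = 3.0


@dataclass
class EvaluationReport:
    """Per-pattern misorientations, success flags and their aggregate rate."""

    threshold_deg: float
    per_pattern: list[dict] = field(default_factory=list)
    sweep: list[dict] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        if not self.per_pattern:
            return float("nan")
        return float(np.mean([p["success"] for p in self.per_pattern]))

    def to_dict(self) -> dict:
        return {
            "threshold_deg": self.threshold_deg,
            "success_rate": self.success_rate,
            "per_pattern": self.per_pattern,
            "sweep": self.sweep,
        }


def _pair_misorientations(
    solutions: list[IndexingSolution],
    truths: list[Rotation],
    symmetry_ops: list[Rotation],
) -> list[float | None]:
    """Greedy minimal-misorientation pairing of solutions to true lattices.

    Returns one entry per true lattice: the misorientation of its matched
    solution, or ``None`` if unmatched.
    """
    pairs = []
    for i, s in enumerate(solutions):
        for j, t in enumerate(truths):
            pairs.append((misorientation(s.rotation, t, symmetry_ops), i, j))
    pairs.sort(key=lambda x: x[0])
    used_s: set[int] = set()
    out: list[float | None] = [None] * len(truths)
    for m, i, j in pairs:
        if i in used_s or out[j] is not None:
            continue
        used_s.add(i)
        out[j] = m
    return out


def evaluate_indexing(
    solutions_per_pattern: list[list[IndexingSolution]],
    truths_per_pattern: list[list[Rotation]],
    threshold_deg: float = CORRECT_THRESHOLD_DEG,
    symmetry_ops: list[Rotation] | None = None,
) -> EvaluationReport:
    """Score solutions against ground truth, one entry per true lattice.

    A lattice counts as correctly indexed iff its matched solution's
    misorientation is *strictly* less than ``threshold_deg``.  Multi-lattice
    patterns are matched greedily by minimal misorientation; unmatched
    lattices count as failures.
    """
    if len(solutions_per_pattern) != len(truths_per_pattern):
        raise EvaluationAlignmentError(
            f"{len(solutions_per_pattern)} solution lists vs "
            f"{len(truths_per_pattern)} truth lists"
        )
    if symmetry_ops is None:
        symmetry_ops = [Rotation.identity()]
    report = EvaluationReport(threshold_deg=threshold_deg)
    for pid, (sols, truths) in enumerate(
        zip(solutions_per_pattern, truths_per_pattern)
    ):
        matched = _pair_misorientations(sols, truths, symmetry_ops)
        for j, m in enumerate(matched):
            report.per_pattern.append(
                {
                    "pattern": pid,
                    "lattice": j,
                    "misorientation_deg": m,
                    "success": bool(m is not None and m < threshold_deg),
                }
            )
    return report


def select_peaks(
    peaks: np.ndarray,
    n: int,
    mode: str,
    rng: np.random.Generator,
    geom: ExperimentGeometry,
) -> np.ndarray:
    """Indices of ``n`` peaks chosen as in reduced-peak-count protocols.

    ``low_resolution`` keeps the peaks with the smallest scattering angles
    (closest to the beam center); ``random`` samples uniformly without
    replacement.
    """
    if n >= len(peaks):
        return np.arange(len(peaks))
    if mode == "low_resolution":
        r = np.hypot(
            peaks[:, 0] - geom.beam_center_px[0], peaks[:, 1] - geom.beam_center_px[1]
        )
        return np.argsort(r, kind="stable")[:n]
    if mode == "random":
        return np.sort(rng.choice(len(peaks), size=n, replace=False))
    raise ValueError("mode must be 'low_resolution' or 'random'")


def make_reduced_pattern(
    pattern: SimulatedPattern,
    n_peaks: int,
    mode: str,
    rng: np.random.Generator,
    spurious_fraction: float = 0.0,
    return_origin: bool = False,
):
    """A peak list of ``n_peaks`` true peaks plus optional spurious admixture.

    Spurious peaks are uniform on the detector with intensities drawn from an
    exponential law at the true peaks' median scale, so that intensity
    ranking cannot trivially reject them; the returned array is shuffled.

    With ``return_origin`` the row indices into the original pattern's
    truth arrays are returned as well (-1 for spurious rows).
    """
    geom = pattern.config.geometry
    true_idx = np.flatnonzero(pattern.truth.spot_crystal >= 0)
    true_peaks = pattern.peaks[true_idx]
    idx = select_peaks(true_peaks, n_peaks, mode, rng, geom)
    sel = true_peaks[idx]
    origin = true_idx[idx]
    n_spur = int(round(spurious_fraction / (1.0 - spurious_fraction) * len(sel)))
    if n_spur:
        nx, ny = geom.detector_shape_px
        spur = np.column_stack(
            [
                rng.uniform(0, nx - 1, n_spur),
                rng.uniform(0, ny - 1, n_spur),
                rng.exponential(max(float(np.median(sel[:, 2])), 1e-12), n_spur),
            ]
        )
        sel = np.vstack([sel, spur])
        origin = np.concatenate([origin, -np.ones(n_spur, dtype=int)])
    perm = rng.permutation(len(sel))
    if return_origin:
        return sel[perm], origin[perm]
    return sel[perm]


def run_sweep(
    base_config: SimulationConfig,
    params: IndexerParams,
    peak_counts: list[int],
    modes: tuple[str, ...] = ("low_resolution", "random"),
    n_patterns: int = 10,
    spurious_fraction: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Success rate versus available peak count, per selection mode.

    For each replicate a fresh pattern is simulated (new orientation), reduced
    to each peak count in each mode, indexed, and scored against the truth at
    the strict 3-degree criterion.  Returns rows
    ``{mode, n_peaks, n_patterns, success_rate}``.
    """
    symmetry_ops = lattice_symmetry_rotations(base_config.cell)
    rows = []
    patterns = []
    for rep in range(n_patterns):
        cfg = replace(base_config, seed=seed + 7919 * (rep + 1))
        patterns.append(simulate_pattern(cfg))
    for mode in modes:
        for n in peak_counts:
            successes = []
            for rep, pat in enumerate(patterns):
                rng = np.random.default_rng(seed + 104729 * (rep + 1) + n)
                n_avail = int((pat.truth.spot_crystal >= 0).sum())
                peaks = make_reduced_pattern(
                    pat, min(n, n_avail), mode, rng, spurious_fraction
                )
                try:
                    sol = index_pattern(
                        peaks,
                        pat.config.geometry,
                        pat.config.spectrum.band,
                        pat.config.cell,
                        params,
                    )
                    m = misorientation(
                        sol.rotation, pat.truth.rotations[0], symmetry_ops
                    )
                    successes.append(m < CORRECT_THRESHOLD_DEG)
                except SnapindexError:
                    successes.append(False)
            rows.append(
                {
                    "mode": mode,
                    "n_peaks": n,
                    "n_patterns": n_patterns,
                    "success_rate": float(np.mean(successes)),
                }
            )
    return rows


def unambiguous_wavelength_mask(
    pattern: SimulatedPattern, origin_idx: np.ndarray
) -> np.ndarray:
    """Flags the spots whose wavelength assignment is well posed.

    A spot is ambiguous when its ULS ray carries more than one in-band RLP
    (collinear harmonics h, 2h, ...): all of them project to the same
    detector position and the excitation wavelength cannot be told apart
    without an energy-resolving detector.  Such spots are excluded from
    wavelength-recovery metrics.
    """
    band = pattern.config.spectrum.band
    out = []
    for o in np.asarray(origin_idx):
        hkl = pattern.truth.spot_hkl[o]
        g = int(np.gcd.reduce(np.abs(hkl))) or 1
        lam = pattern.truth.spot_lambda[o]
        n_inband = 0
        for mlt in range(1, 5 * g + 1):
            lam_m = lam * g / mlt
            if band.lambda_min_A <= lam_m <= band.lambda_max_A:
                n_inband += 1
        out.append(n_inband == 1)
    return np.array(out, dtype=bool)


def series_angles(
    solutions: list[IndexingSolution],
    cell: UnitCell,
    axis: np.ndarray = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Recovered rotation angle (degrees) of each frame relative to frame 0.

    Each frame's orientation is compared with frame 0 after resolving the
    lattice point-group ambiguity (the symmetry image closest to the relative
    rotation of the previous frame is chosen); the angle is signed by the
    projection of the relative rotation vector onto the goniometer axis.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ops = lattice_symmetry_rotations(cell)
    r0 = solutions[0].rotation
    angles = [0.0]
    prev_angle = 0.0
    for sol in solutions[1:]:
        best = None
        for s in ops:
            rel = (sol.rotation @ s) @ r0.inverse()
            ang = np.degrees(rel.angle)
            sign = np.sign(rel.axis @ axis) or 1.0
            signed = sign * ang
            if best is None or abs(signed - prev_angle) < abs(best - prev_angle):
                best = signed
        angles.append(best)
        prev_angle = best
    return np.array(angles)
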