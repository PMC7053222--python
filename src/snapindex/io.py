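"""File formats and logging.

Peak lists are tab-separated text with the header ``x_px  y_px  intensity``;
comment lines start with ``#``.  Geometry, cell, ground truth, solutions and
evaluation reports are JSON.  All indices in files are 0-based; detector
coordinates refer to pixel centers; orientations are stored as unit
quaternions ``(w, x, y, z)`` with ``w >= 0``.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np

from .errors import PeakListParseError
from .geometry import ExperimentGeometry, PeakObservation, UnitCell, WavelengthBand
from .indexer import IndexingSolution
from .rotations import Rotation
from .simulate import GroundTruth

__all__ = [
    "read_peak_list",
    "write_peak_list",
    "read_geometry",
    "read_band",
    "read_cell",
    "write_experiment",
    "write_solution",
    "write_ground_truth",
    "read_ground_truth",
    "setup_logging",
]

PEAK_HEADER = ("x_px", "y_px", "intensity")


def read_peak_list(path: str | Path) -> list[PeakObservation]:
    """Read a TSV peak list, skipping comments and blank lines.

    Raises
    ------
    PeakListParseError
        Naming the offending line on a malformed row.
    """
    peaks: list[PeakObservation] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            fields = s.split()
            if not header_seen:
                if tuple(fields) != PEAK_HEADER:
                    raise PeakListParseError(
                        f"{path}: line {lineno}: expected header "
                        f"'{'  '.join(PEAK_HEADER)}', got {s!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise PeakListParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            try:
                x, y, inten = (float(v) for v in fields)
            except ValueError as exc:
                raise PeakListParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            peaks.append(PeakObservation(x, y, inten))
    if not header_seen:
        raise PeakListParseError(f"{path}: missing header line")
    return peaks


def write_peak_list(path: str | Path, peaks) -> None:
    """Write peaks (PeakObservation iterable or (n, 3) array) as TSV."""
    arr = (
        peaks
        if isinstance(peaks, np.ndarray)
        else np.array([[p.x_px, p.y_px, p.intensity] for p in peaks])
    )
    arr = np.atleast_2d(arr)
    with open(path, "w") as fh:
        fh.write("\t".join(PEAK_HEADER) + "\n")
        for row in arr:
            fh.write(f"{row[0]:.10g}\t{row[1]:.10g}\t{row[2]:.10g}\n")


def read_geometry(path: str | Path) -> ExperimentGeometry:
    """Read detector geometry from a JSON document."""
    doc = json.loads(Path(path).read_text())
    shape = doc.get("detector_shape_px", (2000, 2000))
    return ExperimentGeometry(
        detector_distance_mm=doc["detector_distance_mm"],
        pixel_size_mm=doc["pixel_size_mm"],
        beam_center_px=tuple(doc["beam_center_px"]),
        detector_shape_px=tuple(shape),
    )


def read_band(path: str | Path) -> WavelengthBand:
    """Read the wavelength band from a (possibly combined) JSON document."""
    doc = json.loads(Path(path).read_text())
    return WavelengthBand(doc["lambda_min_A"], doc["lambda_max_A"], doc["lambda_nominal_A"])


def read_cell(path: str | Path) -> UnitCell:
    """Read unit-cell parameters from a JSON document with a ``cell`` key."""
    doc = json.loads(Path(path).read_text())
    c = doc["cell"] if "cell" in doc else doc
    return UnitCell(c["a_A"], c["b_A"], c["c_A"], c["alpha_deg"], c["beta_deg"], c["gamma_deg"])


def write_experiment(
    path: str | Path,
    geom: ExperimentGeometry,
    band: WavelengthBand,
    cell: UnitCell,
) -> None:
    """Write a combined geometry/band/cell JSON usable for both CLI flags."""
    doc = {
        "detector_distance_mm": geom.detector_distance_mm,
        "pixel_size_mm": geom.pixel_size_mm,
        "beam_center_px": list(geom.beam_center_px),
        "detector_shape_px": list(geom.detector_shape_px),
        "lambda_min_A": band.lambda_min_A,
        "lambda_max_A": band.lambda_max_A,
        "lambda_nominal_A": band.lambda_nominal_A,
        "cell": {
            "a_A": cell.a,
            "b_A": cell.b,
            "c_A": cell.c,
            "alpha_deg": cell.alpha,
            "beta_deg": cell.beta,
            "gamma_deg": cell.gamma,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _quat_list(rot: Rotation) -> list[float]:
    return [float(v) for v in rot.quat]


def solution_to_dict(sol: IndexingSolution, params=None, seed=None) -> dict:
    per_peak = []
    for i in range(sol.n_peaks):
        lam = sol.wavelength[i]
        res = sol.residual[i]
        per_peak.append(
            {
                "peak": int(sol.peak_indices[i]),
                "h": int(sol.hkl[i, 0]),
                "k": int(sol.hkl[i, 1]),
                "l": int(sol.hkl[i, 2]),
                "lambda_A": None if not np.isfinite(lam) else float(lam),
                "residual": None if not np.isfinite(res) else float(res),
                "inlier": bool(sol.inlier[i]),
            }
        )
    doc = {
        "reciprocal_basis_rows_invA": [[float(v) for v in row] for row in sol.basis.rows],
        "rotation_quat_wxyz": _quat_list(sol.rotation),
        "score": int(sol.score),
        "rotogram_support": int(sol.support),
        "per_peak": per_peak,
    }
    if params is not None:
        doc["parameters"] = {
            "tolerance": params.tolerance,
            "considered_peaks_count": params.considered_peaks_count,
            "angle_resolution": params.angle_resolution,
            "refinement_type": params.refinement_type,
            "max_lattices": params.max_lattices,
            "min_fitted_fraction": params.min_fitted_fraction,
            "min_peaks": params.min_peaks,
        }
    if seed is not None:
        doc["seed"] = int(seed)
    return doc


def write_solution(
    path: str | Path, solutions: IndexingSolution | list[IndexingSolution], params=None, seed=None
) -> None:
    """Write one pattern's indexing solution(s) as JSON."""
    if isinstance(solutions, IndexingSolution):
        solutions = [solutions]
    doc = {
        "n_lattices": len(solutions),
        "lattices": [solution_to_dict(s, params=params, seed=seed) for s in solutions],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_ground_truth(path: str | Path, truth: GroundTruth, seed=None) -> None:
    doc = {
        "orientations_quat_wxyz": [_quat_list(r) for r in truth.rotations],
        "spots": [
            {
                "peak": i,
                "crystal": int(truth.spot_crystal[i]),
                "h": int(truth.spot_hkl[i, 0]),
                "k": int(truth.spot_hkl[i, 1]),
                "l": int(truth.spot_hkl[i, 2]),
                "lambda_A": None
                if not np.isfinite(truth.spot_lambda[i])
                else float(truth.spot_lambda[i]),
            }
            for i in range(len(truth.spot_crystal))
        ],
    }
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> tuple[list[Rotation], list[dict]]:
    """Read truth orientations and spot records back from JSON."""
    doc = json.loads(Path(path).read_text())
    rots = [Rotation(np.array(q)) for q in doc["orientations_quat_wxyz"]]
    return rots, doc["spots"]


def setup_logging(level: str = "INFO") -> None:
    """Log lines ``LEVEL timestamp message`` to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(asctime)s %(message)s",
        force=True,
    )
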