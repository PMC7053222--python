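"""Geometry layer: reciprocal bases, scattering directions, ULSs, candidates."""

import numpy as np
import pytest

from snapindex.errors import (
    DegeneratePeakError,
    InvalidCellError,
    ResourceLimitError,
)
from snapindex.geometry import (
    ExperimentGeometry,
    PeakObservation,
    UnitCell,
    WavelengthBand,
    build_uls,
    candidate_rlps,
    cell_to_reciprocal_basis,
    generate_rlps,
    pixel_to_direction,
    wavelength_of_q,
)
from snapindex.rotations import random_rotation

from conftest import CELL_TRICLINIC, DEFAULT_GEOMETRY


class TestReciprocalBasis:
    @pytest.mark.parametrize(
        "cell, diag",
        [
            (UnitCell(100, 100, 100, 90, 90, 90), [0.01, 0.01, 0.01]),
            (UnitCell(50, 60, 70, 90, 90, 90), [1 / 50, 1 / 60, 1 / 70]),
        ],
    )
    def test_right_angle_cells_are_diagonal(self, cell, diag):
        b = cell_to_reciprocal_basis(cell)
        assert np.allclose(b.rows, np.diag(diag), atol=1e-15)

    def test_triclinic_duality(self):
        """B A^T = I for a triclinic cell, with A built independently."""
        cell = CELL_TRICLINIC
        ca, cb, cg = (np.cos(np.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
        sg = np.sin(np.radians(cell.gamma))
        v = np.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
        a_rows = np.array(
            [
                [cell.a, 0, 0],
                [cell.b * cg, cell.b * sg, 0],
                [cell.c * cb, cell.c * (ca - cb * cg) / sg, cell.c * v / sg],
            ]
        )
        b = cell_to_reciprocal_basis(cell)
        assert np.allclose(b.rows @ a_rows.T, np.eye(3), atol=1e-12)

    def test_cell_parameters_roundtrip(self):
        b = cell_to_reciprocal_basis(CELL_TRICLINIC)
        c = b.cell_parameters()
        for name in ("a", "b", "c", "alpha", "beta", "gamma"):
            assert getattr(c, name) == pytest.approx(getattr(CELL_TRICLINIC, name), rel=1e-9)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(InvalidCellError):
            UnitCell(50, 60, 70, 10, 10, 170)  # violates metric positivity

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidCellError):
            UnitCell(-5, 60, 70, 90, 90, 90)


class TestPixelToDirection:
    def test_beam_center_maps_to_beam(self):
        n = pixel_to_direction(PeakObservation(999.5, 999.5, 1.0), DEFAULT_GEOMETRY)
        assert np.allclose(n, [0, 0, 1], atol=1e-15)

    def test_45_degree_scattering(self):
        """Lateral displacement equal to the distance gives a 45-degree ray."""
        geom = ExperimentGeometry(100.0, 0.1, (0.0, 0.0))
        n = pixel_to_direction(PeakObservation(1000.0, 0.0, 1.0), geom)  # 100 mm
        assert n[2] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetry(self):
        geom = DEFAULT_GEOMETRY
        cx, cy = geom.beam_center_px
        n1 = pixel_to_direction(PeakObservation(cx + 300, cy + 120, 1), geom)
        n2 = pixel_to_direction(PeakObservation(cx - 300, cy - 120, 1), geom)
        assert np.allclose(n1[:2], -n2[:2], atol=1e-14)
        assert n1[2] == pytest.approx(n2[2], abs=1e-14)


class TestBuildUls:
    def test_monochromatic_point(self):
        """At 2-theta = 30 degrees the segment degenerates to |q| = 2 sin(15)."""
        band = WavelengthBand.monochromatic(1.0)
        two_theta = np.radians(30.0)
        n = np.array([np.sin(two_theta), 0.0, np.cos(two_theta)])
        uls = build_uls(n, band)
        expect = 2 * np.sin(two_theta / 2)
        assert uls.q_min == pytest.approx(expect, rel=1e-12)
        assert uls.q_max == pytest.approx(expect, rel=1e-12)

    def test_band_endpoints(self):
        band = WavelengthBand(0.95, 1.05, 1.0)
        two_theta = np.radians(30.0)
        n = np.array([np.sin(two_theta), 0.0, np.cos(two_theta)])
        uls = build_uls(n, band)
        e = 2 * np.sin(two_theta / 2)
        assert uls.q_min == pytest.approx(e / 1.05, rel=1e-12)
        assert uls.q_max == pytest.approx(e / 0.95, rel=1e-12)

    def test_forward_beam_degenerate(self):
        with pytest.raises(DegeneratePeakError):
            build_uls(np.array([0.0, 0.0, 1.0]), WavelengthBand.monochromatic(1.0))

    def test_elastic_reconstruction(self, rng):
        """Every segment point satisfies the elastic condition for some
        in-band wavelength with the original scattering direction."""
        band = WavelengthBand(0.9, 1.1, 1.0)
        for _ in range(200):
            v = rng.normal(size=3)
            v[2] = abs(v[2]) + 0.3
            n = v / np.linalg.norm(v)
            uls = build_uls(n, band)
            for t in np.linspace(uls.q_min, uls.q_max, 7):
                q = t * uls.direction
                lam = wavelength_of_q(q[None, :])[0]
                assert band.lambda_min_A - 1e-12 <= lam <= band.lambda_max_A + 1e-12
                n_back = lam * q + np.array([0, 0, 1.0])
                assert np.allclose(n_back, n, atol=1e-10)


class TestGenerateRlps:
    def test_below_shortest_vector_empty(self):
        b = cell_to_reciprocal_basis(UnitCell(100, 100, 100, 90, 90, 90))
        assert len(generate_rlps(b, 0.005)) == 0

    def test_cubic_count_matches_brute_force(self):
        b = cell_to_reciprocal_basis(UnitCell(100, 100, 100, 90, 90, 90))
        got = generate_rlps(b, 0.0245)
        count = 0
        for h in range(-3, 4):
            for k in range(-3, 4):
                for l in range(-3, 4):
                    if (h, k, l) != (0, 0, 0) and 0.01 * np.sqrt(
                        h * h + k * k + l * l
                    ) <= 0.0245:
                        count += 1
        assert len(got) == count == 80

    def test_friedel_closure_and_order(self):
        b = cell_to_reciprocal_basis(CELL_TRICLINIC)
        rl = generate_rlps(b, 0.05)
        keys = {tuple(h) for h in rl.hkl}
        assert {tuple(-h) for h in rl.hkl} == keys
        assert np.all(np.diff(rl.norms) >= -1e-12)  # sorted by norm

    def test_resource_limit(self):
        b = cell_to_reciprocal_basis(UnitCell(100, 100, 100, 90, 90, 90))
        with pytest.raises(ResourceLimitError):
            generate_rlps(b, 1.0, max_points=1000)


class TestCandidateRlps:
    def test_sphere_boundary_at_zero_tolerance(self):
        b = cell_to_reciprocal_basis(UnitCell(100, 100, 100, 90, 90, 90))
        rl = generate_rlps(b, 0.05)
        band = WavelengthBand.monochromatic(1.0)
        # direction whose |e| equals the (1,0,0) norm exactly
        q = 0.01
        theta = np.arcsin(q / 2)
        n = np.array([np.sin(2 * theta), 0, np.cos(2 * theta)])
        uls = build_uls(n, band)
        included = candidate_rlps(uls, rl, 0.0)
        assert np.all(np.isclose(included.norms, q, rtol=1e-9))
        off = build_uls(n, WavelengthBand.monochromatic(1.0 * (1 + 1e-6)))
        shifted = candidate_rlps(off, rl, 0.0)
        assert len(shifted) == 0  # 1e-6 relative offset excludes the shell

    def test_matches_brute_force_norm_filter(self, rng):
        b = cell_to_reciprocal_basis(CELL_TRICLINIC)
        rl = generate_rlps(b, 0.08)
        band = WavelengthBand(0.975, 1.025, 1.0)
        for _ in range(50):
            v = rng.normal(size=3)
            v[2] = abs(v[2]) + 1.0
            uls = build_uls(v / np.linalg.norm(v), band)
            got = candidate_rlps(uls, rl, 0.02)
            lo, hi = 0.98 * uls.q_min, 1.02 * uls.q_max
            expect = {tuple(h) for h, nn in zip(rl.hkl, rl.norms) if lo <= nn <= hi}
            assert {tuple(h) for h in got.hkl} == expect

    def test_rotation_invariance(self, rng):
        cell = CELL_TRICLINIC
        b = cell_to_reciprocal_basis(cell)
        rot = random_rotation(rng).as_matrix()
        b_rot = b.rotated(rot)
        band = WavelengthBand(0.95, 1.05, 1.0)
        v = np.array([0.4, -0.2, 1.0])
        uls = build_uls(v / np.linalg.norm(v), band)
        n1 = len(candidate_rlps(uls, generate_rlps(b, 0.06), 0.01))
        n2 = len(candidate_rlps(uls, generate_rlps(b_rot, 0.06), 0.01))
        assert n1 == n2

    def test_monotone_in_bandwidth(self):
        b = cell_to_reciprocal_basis(CELL_TRICLINIC)
        rl = generate_rlps(b, 0.08)
        v = np.array([0.3, 0.1, 1.0])
        n = v / np.linalg.norm(v)
        prev: set = set()
        for half in (0.0, 0.01, 0.03, 0.06, 0.1):
            band = WavelengthBand(1 - half, 1 + half, 1.0)
            got = {tuple(h) for h in candidate_rlps(build_uls(n, band), rl, 0.01).hkl}
            assert prev <= got
            prev = got
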