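"""Nearest-RLP assignment, distance oracle, gradient-descent refinement."""

import numpy as np
import pytest

from snapindex.errors import InsufficientInliersError
from snapindex.geometry import (
    UncertaintyLineSegment,
    build_ulss,
    cell_to_reciprocal_basis,
    generate_rlps,
)
from snapindex.refine import (
    RefinementConfig,
    assign_nearest_rlps,
    point_segment_distance,
    refine_solution,
    score_solution,
)
from snapindex.rotations import (
    Rotation,
    lattice_symmetry_rotations,
    misorientation,
    orientation_of_basis,
    random_rotation,
)
from snapindex.simulate import simulate_pattern

from conftest import CELL_PINK, PINK, pink_config


def _pattern_ulss(pat):
    band = pat.config.spectrum.band
    ulss, valid = build_ulss(pat.peaks[:, :2], pat.config.geometry, band)
    return [u for u, v in zip(ulss, valid) if v]


@pytest.fixture(scope="module")
def pink_setup():
    """Noise-free pink pattern: exact lattice data for refinement tests."""
    pat = simulate_pattern(pink_config(seed=11))
    b0 = cell_to_reciprocal_basis(CELL_PINK)
    b_true = b0.rotated(pat.truth.rotations[0].as_matrix())
    return pat, b0, b_true, _pattern_ulss(pat)


class TestPointSegmentDistance:
    def test_midpoint_zero(self):
        uls = UncertaintyLineSegment(np.array([0, 0, 1.0]), 0.1, 0.3)
        assert point_segment_distance(np.array([0, 0, 0.2]), uls) == 0.0

    def test_beyond_far_endpoint(self):
        uls = UncertaintyLineSegment(np.array([0, 0, 1.0]), 0.1, 0.3)
        assert point_segment_distance(np.array([0, 0, 0.45]), uls) == pytest.approx(0.15)

    def test_agrees_with_dense_sampling(self, rng):
        ts = np.linspace(0.0, 1.0, 100_000)
        for _ in range(100):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            qmin = rng.uniform(0.05, 0.2)
            qmax = qmin + rng.uniform(0.0, 0.2)
            uls = UncertaintyLineSegment(d, qmin, qmax)
            q = rng.normal(size=3) * 0.3
            sampled = np.min(
                np.linalg.norm(
                    q[None, :] - (qmin + ts * (qmax - qmin))[:, None] * d[None, :],
                    axis=1,
                )
            )
            assert point_segment_distance(q, uls) == pytest.approx(sampled, abs=1e-8)


class TestAssignNearest:
    def test_exact_lattice_recovers_truth(self, pink_setup):
        pat, b0, b_true, ulss = pink_setup
        a = assign_nearest_rlps(b_true, ulss, 0.02)
        assert np.all(a.distance <= 1e-9)
        assert a.n_inliers == len(ulss)
        # assigned hkl reproduce the true scattering vectors
        q_fit = a.hkl @ b_true.rows
        q_true = pat.truth.spot_hkl @ b_true.rows
        assert np.allclose(np.linalg.norm(q_fit, axis=1), np.linalg.norm(q_true, axis=1), atol=1e-9)

    def test_matches_brute_force(self, rng):
        b = cell_to_reciprocal_basis(CELL_PINK)
        rot = random_rotation(rng)
        b = b.rotated(rot.as_matrix())
        rl = generate_rlps(b, 0.45)
        for _ in range(30):
            v = rng.normal(size=3)
            v[2] = abs(v[2]) + 1.0
            n = v / np.linalg.norm(v)
            e = n - np.array([0, 0, 1.0])
            ne = np.linalg.norm(e)
            uls = UncertaintyLineSegment(e / ne, ne / 1.125, ne / 0.875)
            if uls.q_max > 0.4:
                continue
            a = assign_nearest_rlps(b, [uls], 0.02)
            dists = np.array([point_segment_distance(q, uls) for q in rl.q0])
            assert a.distance[0] == pytest.approx(dists.min(), abs=1e-10)

    def test_inlier_threshold_boundary(self):
        b = cell_to_reciprocal_basis(CELL_PINK)
        hkl = np.array([2, 1, 3])
        q = hkl @ b.rows
        qn = np.linalg.norm(q)
        d = q / qn
        tol = 0.02
        for off, flag in ((0.99, True), (1.01, False)):
            # place the segment so the nearest endpoint is off * tol * |q| away
            shift = off * tol * qn
            uls = UncertaintyLineSegment(d, qn + shift, qn + shift + 0.01)
            a = assign_nearest_rlps(b, [uls], tol)
            assert bool(a.inlier[0]) is flag

    def test_empty_input(self):
        b = cell_to_reciprocal_basis(CELL_PINK)
        a = assign_nearest_rlps(b, [], 0.02)
        assert a.n_inliers == 0 and len(a.hkl) == 0


class TestScore:
    def test_true_basis_scores_all(self, pink_setup):
        _, _, b_true, ulss = pink_setup
        assert score_solution(b_true, ulss, 0.02) == len(ulss)

    def test_zero_tolerance_with_offset_scores_zero(self, pink_setup):
        _, _, b_true, ulss = pink_setup
        jittered = []
        rng = np.random.default_rng(0)
        for u in ulss:
            d = u.direction + rng.normal(scale=1e-3, size=3)
            d /= np.linalg.norm(d)
            jittered.append(UncertaintyLineSegment(d, u.q_min, u.q_max))
        assert score_solution(b_true, jittered, 0.0) == 0


class TestRefine:
    def test_true_basis_is_fixed_point(self, pink_setup):
        _, _, b_true, ulss = pink_setup
        cfg = RefinementConfig()
        out = refine_solution(b_true, ulss, cfg, 0.02)
        assert np.allclose(out.rows, b_true.rows, atol=1e-9)

    @pytest.mark.parametrize(
        "mode", ["fixedLatticeParameters", "fitAllLatticeParameters"]
    )
    def test_recovers_one_degree_perturbation(self, pink_setup, mode):
        pat, b0, b_true, ulss = pink_setup
        truth = pat.truth.rotations[0]
        perturb = Rotation.from_axis_angle([0.2, -0.5, 0.8], np.radians(1.0))
        start = b0.rotated((perturb @ truth).as_matrix())
        out = refine_solution(start, ulss, RefinementConfig(refinement_type=mode), 0.02)
        ops = lattice_symmetry_rotations(CELL_PINK)
        m = misorientation(orientation_of_basis(out.rows, b0.rows), truth, ops)
        assert m <= 0.1

    def test_fixed_mode_preserves_cell(self, pink_setup):
        pat, b0, b_true, ulss = pink_setup
        truth = pat.truth.rotations[0]
        perturb = Rotation.from_axis_angle([1.0, 0.2, 0.1], np.radians(0.8))
        start = b0.rotated((perturb @ truth).as_matrix())
        out = refine_solution(start, ulss, RefinementConfig(), 0.02)
        got = out.cell_parameters()
        for name in ("a", "b", "c", "alpha", "beta", "gamma"):
            assert getattr(got, name) == pytest.approx(
                getattr(CELL_PINK, name), rel=1e-9
            )

    def test_outliers_do_not_move_the_solution(self, pink_setup, rng):
        """Far-off spurious segments are excluded from the objective."""
        _, _, b_true, ulss = pink_setup
        spurious = []
        for _ in range(5):
            d = rng.normal(size=3)
            d[2] = -abs(d[2]) - 0.5
            d /= np.linalg.norm(d)
            spurious.append(UncertaintyLineSegment(d, 0.171717, 0.171718))
        out_clean = refine_solution(b_true, ulss, RefinementConfig(), 0.02)
        out_spur = refine_solution(b_true, ulss + spurious, RefinementConfig(), 0.02)
        assert np.allclose(out_clean.rows, out_spur.rows, atol=1e-9)

    def test_too_few_inliers_raises(self, rng):
        b = cell_to_reciprocal_basis(CELL_PINK)
        ulss = []
        for _ in range(4):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ulss.append(UncertaintyLineSegment(d, 0.31111, 0.31112))
        with pytest.raises(InsufficientInliersError):
            refine_solution(b, ulss, RefinementConfig(), 1e-7)

    def test_none_mode_is_identity(self, pink_setup):
        _, _, b_true, ulss = pink_setup
        out = refine_solution(
            b_true, ulss, RefinementConfig(refinement_type="none"), 0.02
        )
        assert out is b_true
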