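"""End-to-end indexing across the three regimes, prediction, wavelengths."""

import numpy as np
import pytest
from dataclasses import replace

from snapindex.errors import InsufficientPeaksError, SnapindexError
from snapindex.evaluate import evaluate_indexing, make_reduced_pattern
from snapindex.geometry import cell_to_reciprocal_basis
from snapindex.indexer import (
    IndexerParams,
    index_multi,
    index_pattern,
    predict_reflections,
)
from snapindex.rotations import lattice_symmetry_rotations, misorientation
from snapindex.simulate import simulate_pattern

from conftest import (
    CELL_ORTHO,
    CELL_PINK,
    MONO,
    MONO_PARAMS,
    PINK,
    PINK_PARAMS,
    mono_config,
    pink_config,
)

OPS_ORTHO = lattice_symmetry_rotations(CELL_ORTHO)
OPS_PINK = lattice_symmetry_rotations(CELL_PINK)


class TestIndexPattern:
    def test_monochromatic_forty_peaks(self, rng):
        pat = simulate_pattern(mono_config(seed=30))
        peaks = make_reduced_pattern(pat, 40, "random", rng)
        sol = index_pattern(peaks, pat.config.geometry, MONO.band, CELL_ORTHO, MONO_PARAMS)
        m = misorientation(sol.rotation, pat.truth.rotations[0], OPS_ORTHO)
        assert m < 3.0
        assert sol.score >= 0.9 * len(peaks)

    def test_pink_beam_sixty_peaks(self, rng):
        pat = simulate_pattern(pink_config(seed=31))
        peaks = make_reduced_pattern(pat, 60, "random", rng)
        sol = index_pattern(peaks, pat.config.geometry, PINK.band, CELL_PINK, PINK_PARAMS)
        m = misorientation(sol.rotation, pat.truth.rotations[0], OPS_PINK)
        assert m < 3.0
        band = PINK.band
        lam = sol.wavelength[sol.inlier]
        assert np.all((lam >= band.lambda_min_A) & (lam <= band.lambda_max_A))

    def test_noise_only_gives_no_solution(self):
        """Random peaks in the study's resolution annulus never index.

        Positions are drawn uniformly over the detector annulus used by the
        simulated studies (peak lists are resolution-limited in practice).
        """
        geom = mono_config(seed=0).geometry
        # radii corresponding to |q| in ~[0.08, 0.25] at 1 A
        r_lo, r_hi = 80, 256
        failures = 0
        for seed in range(6):
            rng = np.random.default_rng(1000 + seed)
            r = np.sqrt(rng.uniform(r_lo**2, r_hi**2, 40))
            phi = rng.uniform(0, 2 * np.pi, 40)
            x = np.clip(geom.beam_center_px[0] + r * np.cos(phi), 0, 1999)
            y = np.clip(geom.beam_center_px[1] + r * np.sin(phi), 0, 1999)
            peaks = np.column_stack([x, y, rng.exponential(1.0, 40)])
            try:
                index_pattern(peaks, geom, MONO.band, CELL_ORTHO, MONO_PARAMS)
            except SnapindexError:
                failures += 1
        assert failures == 6

    def test_too_few_peaks(self):
        geom = mono_config(seed=0).geometry
        peaks = np.array([[500.0, 500.0, 1.0]] * 4)
        with pytest.raises(InsufficientPeaksError):
            index_pattern(peaks, geom, MONO.band, CELL_ORTHO, MONO_PARAMS)

    def test_deterministic(self, rng):
        pat = simulate_pattern(mono_config(seed=32))
        peaks = make_reduced_pattern(pat, 40, "random", rng)
        s1 = index_pattern(peaks, pat.config.geometry, MONO.band, CELL_ORTHO, MONO_PARAMS)
        s2 = index_pattern(peaks, pat.config.geometry, MONO.band, CELL_ORTHO, MONO_PARAMS)
        assert np.array_equal(s1.basis.rows, s2.basis.rows)
        assert np.array_equal(s1.hkl, s2.hkl)


class TestIndexMulti:
    def test_two_crystals_recovered(self):
        cfg = mono_config(seed=33, n_crystals=2)
        pat = simulate_pattern(cfg)
        params = replace(MONO_PARAMS, max_lattices=2, grid_n_override=201)
        sols = index_multi(pat.peaks, cfg.geometry, MONO.band, CELL_ORTHO, params)
        assert len(sols) == 2
        report = evaluate_indexing([sols], [pat.truth.rotations], 3.0, OPS_ORTHO)
        assert all(r["success"] for r in report.per_pattern)
        assert sols[0].score >= sols[1].score

    def test_single_crystal_single_solution(self):
        cfg = mono_config(seed=34)
        pat = simulate_pattern(cfg)
        params = replace(MONO_PARAMS, max_lattices=3)
        sols = index_multi(pat.peaks, cfg.geometry, MONO.band, CELL_ORTHO, params)
        assert len(sols) == 1

    def test_max_lattices_cap(self):
        cfg = mono_config(seed=33, n_crystals=2)
        pat = simulate_pattern(cfg)
        params = replace(MONO_PARAMS, max_lattices=1, grid_n_override=201)
        sols = index_multi(pat.peaks, cfg.geometry, MONO.band, CELL_ORTHO, params)
        assert len(sols) == 1


class TestPredictReflections:
    def test_positive_wavelength_only(self, pink_pattern):
        b0 = cell_to_reciprocal_basis(CELL_PINK)
        basis = b0.rotated(pink_pattern.truth.rotations[0].as_matrix())
        pred = predict_reflections(basis, PINK.band, pink_pattern.config.geometry, 0.45)
        q = pred["q"]
        assert np.all(q[:, 2] < 0)
        assert np.all(
            (pred["lambda_A"] >= PINK.band.lambda_min_A)
            & (pred["lambda_A"] <= PINK.band.lambda_max_A)
        )

    def test_elastic_condition_on_ewald_sphere(self, pink_pattern):
        b0 = cell_to_reciprocal_basis(CELL_PINK)
        basis = b0.rotated(pink_pattern.truth.rotations[0].as_matrix())
        pred = predict_reflections(basis, PINK.band, pink_pattern.config.geometry, 0.45)
        q, lam = pred["q"], pred["lambda_A"]
        center_dist = np.linalg.norm(q + np.array([0, 0, 1.0]) / lam[:, None], axis=1)
        assert np.allclose(center_dist, 1.0 / lam, atol=1e-9)

    def test_round_trip_reproduces_simulated_positions(self, pink_pattern):
        """Predictions at the true orientation hit the simulated spots."""
        b0 = cell_to_reciprocal_basis(CELL_PINK)
        basis = b0.rotated(pink_pattern.truth.rotations[0].as_matrix())
        cfg = pink_pattern.config
        pred = predict_reflections(basis, PINK.band, cfg.geometry, cfg.q_cutoff)
        lut = {tuple(h): (x, y) for h, x, y in zip(pred["hkl"], pred["x_px"], pred["y_px"])}
        t = pink_pattern.truth
        lattice = np.flatnonzero(t.spot_crystal >= 0)
        checked = 0
        for i in lattice:
            key = tuple(t.spot_hkl[i])
            if key in lut:
                assert np.hypot(
                    lut[key][0] - t.spot_true_xy[i, 0],
                    lut[key][1] - t.spot_true_xy[i, 1],
                ) <= 1e-6
                checked += 1
        assert checked >= 0.95 * len(lattice)


class TestWavelengths:
    def test_pink_wavelengths_recovered(self, rng):
        pat = simulate_pattern(pink_config(seed=35))
        peaks, origin = make_reduced_pattern(pat, 60, "random", rng, return_origin=True)
        sol = index_pattern(peaks, pat.config.geometry, PINK.band, CELL_PINK, PINK_PARAMS)
        inl = np.flatnonzero(sol.inlier & (origin >= 0))
        lam_fit = sol.wavelength[inl]
        lam_true = pat.truth.spot_lambda[origin[inl]]
        rel = np.abs(lam_fit - lam_true) / lam_true
        # all but harmonically ambiguous peaks recover the excitation
        assert np.median(rel) <= 1e-4
        assert np.mean(rel <= 1e-3) >= 0.9

    def test_outliers_have_nan_wavelength(self, rng):
        pat = simulate_pattern(pink_config(seed=36))
        peaks = make_reduced_pattern(pat, 50, "random", rng, spurious_fraction=0.2)
        sol = index_pattern(peaks, pat.config.geometry, PINK.band, CELL_PINK, PINK_PARAMS)
        assert np.all(np.isnan(sol.wavelength[~sol.inlier]))
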