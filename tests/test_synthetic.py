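"""Generator contracts: determinism, ground-truth consistency, closed forms."""

import numpy as np
import pytest

from erythrokit import presets
from erythrokit.morphology import radial_profile, segment_cells
from erythrokit.synthetic import (
    CellComposition,
    MeshParams,
    TextureParams,
    make_cell_scene,
    make_current_trace,
    make_cytoskeleton_image,
    make_extinction_table,
    make_force_curve,
    make_spectrum,
    make_surface_texture,
)
from erythrokit.synthetic.cells import largest_remainder_counts
from erythrokit.synthetic.surface import AMPLITUDE_FACTOR


class TestSurfaceTexture:
    def test_zero_amplitude_is_flat(self):
        with pytest.raises(ValueError):
            TextureParams(0.0, 939.0, 0.0, 0.0)  # L2 = 0 invalid
        m = make_surface_texture(TextureParams(0.0, 939.0, 0.0, 98.5), size=128)
        assert np.all(m.heights == 0.0)

    def test_single_band_rms_closed_form(self):
        # ensemble of equal-amplitude sinusoids: total RMS = h1 / (2*sqrt(2))
        m = make_surface_texture(TextureParams(2.0, 500.0, 0.0, 98.5),
                                 size=256, seed=5)
        assert np.std(m.heights) == pytest.approx(2.0 / AMPLITUDE_FACTOR, rel=0.02)

    def test_deterministic_given_seed(self):
        a = make_surface_texture(presets.TEXTURE_PRESETS["control"], size=256,
                                 pixel_size=15.0, seed=9)
        b = make_surface_texture(presets.TEXTURE_PRESETS["control"], size=256,
                                 pixel_size=15.0, seed=9)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_unresolvable_period_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            make_surface_texture(TextureParams(1.0, 2000.0, 1.0, 98.5),
                                 size=128, pixel_size=10.0)

    def test_band_rms_calibration_both_bands(self):
        # band-filtered RMS matches h_k/(2*sqrt(2)) within 5% per seed
        from erythrokit.metrology import decompose_bands
        params = presets.TEXTURE_PRESETS["control"]
        for seed in range(6):
            m = make_surface_texture(params, size=512, seed=seed)
            low, high = decompose_bands(m, 300.0)
            assert np.std(low.heights) == pytest.approx(
                params.h1 / AMPLITUDE_FACTOR, rel=0.05)
            assert np.std(high.heights) == pytest.approx(
                params.h2 / AMPLITUDE_FACTOR, rel=0.05)


class TestCellScene:
    def test_composition_invariants(self):
        with pytest.raises(ValueError):
            CellComposition(50.0, 30.0, 10.0)   # sums to 90
        with pytest.raises(ValueError):
            CellComposition(120.0, -10.0, -10.0)

    def test_largest_remainder_rounding(self):
        comp = CellComposition(54.0, 42.0, 4.0)
        counts = largest_remainder_counts(comp, 100)
        assert counts == {"discocyte": 54, "echinocyte": 42, "codocyte": 4}
        counts = largest_remainder_counts(CellComposition(100 / 3, 100 / 3, 100 / 3), 10)
        assert sum(counts.values()) == 10

    def test_single_class_scene_biconcave(self):
        scene, truth = make_cell_scene(CellComposition(100, 0, 0), n_cells=5, seed=2)
        assert len(truth) == 5
        assert all(t.label == "discocyte" for t in truth)
        cells = segment_cells(scene)
        assert len(cells) == 5
        for cell in cells:
            profile, _ = radial_profile(scene, cell)
            assert profile[0] < profile.max()        # centre below rim

    def test_ground_truth_geometry_per_class(self):
        scene, truth = make_cell_scene(CellComposition(34, 33, 33), n_cells=9, seed=4)
        cells = segment_cells(scene)
        by_pos = {tuple(np.round(c.centroid, -1)): c for c in cells}
        for t in truth:
            key = tuple(np.round(t.center, -1))
            cell = by_pos.get(key)
            if cell is None:
                cell = min(cells, key=lambda c: (c.centroid[0] - t.center[0]) ** 2
                           + (c.centroid[1] - t.center[1]) ** 2)
            profile, angular = radial_profile(scene, cell)
            if t.label == "discocyte":
                assert profile[0] < profile.max()
            elif t.label == "codocyte":
                assert profile[0] > profile[2]       # centre is a local max
                n = len(profile)
                assert profile[n // 3:2 * n // 3].min() < profile[0]
            else:  # echinocyte: >= 10 angular rim maxima
                a = angular - angular.mean()
                sign = np.sign(a)
                crossings = np.sum(np.abs(np.diff(sign)) > 0)
                assert crossings >= 2 * 10

    def test_overfull_field_raises(self):
        from erythrokit.synthetic.cells import PlacementError
        with pytest.raises(PlacementError):
            make_cell_scene(CellComposition(100, 0, 0), n_cells=40, seed=1,
                            pixel_size=40.0, field_px=512, max_tries=200)

    def test_deterministic_given_seed(self):
        a, ta = make_cell_scene(CellComposition(100, 0, 0), n_cells=3, seed=7)
        b, tb = make_cell_scene(CellComposition(100, 0, 0), n_cells=3, seed=7)
        np.testing.assert_array_equal(a.heights, b.heights)
        assert [t.center for t in ta] == [t.center for t in tb]


class TestCytoskeletonMesh:
    def test_poisson_count_around_intensity(self):
        counts = [len(make_cytoskeleton_image(presets.MESH_PRESETS["control"],
                                              size=512, seed=s)[1])
                  for s in range(5)]
        # interior ground-truth pores: Poisson(125) minus border exclusions
        assert 80 <= np.mean(counts) <= 140

    def test_ground_truth_feret_matches_target(self):
        ferets = []
        for s in range(5):
            _, truth = make_cytoskeleton_image(presets.MESH_PRESETS["control"],
                                               size=512, seed=s)
            ferets.append(np.mean([t.feret_um for t in truth]))
        assert np.mean(ferets) == pytest.approx(0.13, rel=0.10)

    def test_deterministic_quadrant_fixture(self):
        pts = np.array([[500, 500], [500, 1500], [1500, 500], [1500, 1500]], float)
        params = MeshParams(pore_density=4, mean_pore_length=0.5)
        _, truth = make_cytoskeleton_image(params, size=256, seed_points_nm=pts,
                                           noise_sd=0.0)
        assert len(truth) == 4
        for t in truth:
            assert t.feret_um == pytest.approx(0.5, rel=0.02)

    def test_ridge_width_validation(self):
        with pytest.raises(ValueError, match="ridge_width"):
            make_cytoskeleton_image(MeshParams(125.0, 0.13, ridge_width=500.0),
                                    size=256, seed=0)


class TestForceCurveGenerator:
    def test_no_contact_flat_curve(self):
        s = make_force_curve(4.1, max_indentation=0.0, noise_sd=0.0)
        assert np.allclose(s.y, 0.0)

    def test_hertz_linearity_in_modulus(self):
        # doubling E doubles deflection-derived force at fixed indentation
        a = make_force_curve(3.0, noise_sd=0.0)
        b = make_force_curve(6.0, noise_sd=0.0)
        da, db = a.y, b.y
        delta_a = (a.x - 500.0) - da
        delta_b = (b.x - 500.0) - db
        # compare forces at matched indentation via interpolation
        grid = np.linspace(100, 600, 40)
        Fa = np.interp(grid, delta_a[delta_a > 0], da[delta_a > 0])
        Fb = np.interp(grid, delta_b[delta_b > 0], db[delta_b > 0])
        np.testing.assert_allclose(Fb / Fa, 2.0, rtol=0.01)

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            make_force_curve(0.0)


class TestSpectraGenerators:
    def test_extinction_maxima_positions(self):
        t = make_extinction_table()
        w = t.wavelengths
        from scipy.signal import argrelmax
        assert list(w[argrelmax(t.eps_HbO2)[0]]) == [542.0, 577.0]
        assert w[np.argmax(t.eps_Hb)] == 555.0
        assert (t.eps_HbO2 > 0).all() and (t.eps_Hb > 0).all() and (t.eps_MetHb > 0).all()

    def test_grid_coverage_required(self):
        with pytest.raises(ValueError):
            make_extinction_table(np.arange(520.0, 700.0))

    def test_single_species_spectrum(self):
        t = make_extinction_table()
        s = make_spectrum((0, 0, 100), M=0.01, S=1e8, table=t, noise_sd=0.0)
        expected = t.eps_MetHb * 1.0 + 0.01 + 1e8 / t.wavelengths**4
        np.testing.assert_allclose(s.y, expected, rtol=1e-12)

    def test_zero_spectrum(self):
        s = make_spectrum((85, 15, 0), total_conc=0.0, M=0.0, S=0.0, noise_sd=0.0)
        assert np.allclose(s.y, 0.0)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum((105, -5, 0))


class TestCurrentTrace:
    def test_noiseless_plateau(self):
        s = make_current_trace(0.0, 10.0, noise_sd=0.0)
        assert s.y.max() == pytest.approx(10.0, abs=1e-6)

    def test_peak_must_exceed_baseline(self):
        with pytest.raises(ValueError):
            make_current_trace(5.0, 5.0)

    def test_noisy_max_within_extreme_value_bound(self):
        from erythrokit.ros import max_current
        sd = 1.0
        maxima = [max_current(make_current_trace(0.0, 10.0, noise_sd=sd, seed=s))
                  for s in range(20)]
        assert np.all(np.abs(np.asarray(maxima) - 10.0) < 3.0 * sd)
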