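"""Fourier metrology: flattening, PSD, band decomposition, parameter estimates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erythrokit import (
    HeightMap,
    InsufficientDataError,
    band_params,
    decompose_bands,
    flatten,
    radial_psd,
    surface_params,
)
from erythrokit import presets
from erythrokit.metrology import _lowpass_mask
from erythrokit.synthetic import TextureParams, make_surface_texture


def sinusoid_map(period_nm: float, amplitude: float = 1.0, n: int = 256,
                 pixel: float = 10.0) -> HeightMap:
    y, x = np.mgrid[0:n, 0:n] * pixel
    return HeightMap(amplitude * np.sin(2 * np.pi * x / period_nm), pixel)


class TestFlatten:
    def test_plane_removed_exactly(self):
        y, x = np.mgrid[0:64, 0:64].astype(float)
        hm = HeightMap(3.0 + 0.1 * x, 10.0)
        res = flatten(hm, order=1)
        assert np.abs(res.heights).max() < 1e-9

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            flatten(HeightMap(np.zeros((8, 8)), 10.0), order=0)

    def test_too_small_map(self):
        with pytest.raises(InsufficientDataError):
            flatten(HeightMap(np.zeros((1, 2)), 10.0), order=2)

    def test_texture_recovered_after_paraboloid_background(self):
        params = TextureParams(2.7, 939.0, 0.9, 98.5)
        tex = make_surface_texture(params, size=256, pixel_size=15.0, seed=8)
        y, x = np.mgrid[0:256, 0:256].astype(float) / 256.0
        bg = 500.0 * ((x - 0.5) ** 2 + (y - 0.5) ** 2)
        curved = HeightMap(tex.heights + bg, tex.pixel_size)
        sp_ref = surface_params(tex, flatten_order=2)
        sp_cur = surface_params(curved, flatten_order=2)
        assert sp_cur.h1 == pytest.approx(sp_ref.h1, rel=0.05)
        assert sp_cur.h2 == pytest.approx(sp_ref.h2, rel=0.05)


class TestRadialPSD:
    def test_single_sinusoid_peak_position(self):
        psd = radial_psd(sinusoid_map(100.0))
        f_peak = psd.spatial_frequency[np.argmax(psd.power)]
        assert f_peak == pytest.approx(0.01, abs=psd.bin_width)

    def test_white_noise_flat_spectrum(self):
        # azimuthal-mean PSD of white noise is flat; average over 20 seeds
        acc = None
        for s in range(20):
            z = np.random.default_rng(s).normal(0, 1, (128, 128))
            p = radial_psd(HeightMap(z, 10.0))
            acc = p.power if acc is None else acc + p.power
        mean_psd = acc / 20
        inside = p.spatial_frequency < 0.04          # clear of the Nyquist corners
        cv = np.std(mean_psd[inside]) / np.mean(mean_psd[inside])
        assert cv < 0.1

    def test_parseval_total_power(self):
        z = np.random.default_rng(3).normal(0, 2.0, (256, 256))
        psd = radial_psd(HeightMap(z, 10.0))
        assert psd.total_power() == pytest.approx(z.var(), rel=0.03)

    def test_zero_map_zero_power(self):
        psd = radial_psd(HeightMap(np.zeros((64, 64)), 10.0))
        assert np.all(psd.power == 0.0)

    def test_degenerate_map_rejected(self):
        with pytest.raises(InsufficientDataError):
            radial_psd(HeightMap(np.zeros((4, 4)), 10.0))


class TestDecomposeBands:
    def test_exact_reconstruction(self, control_texture):
        low, high = decompose_bands(control_texture, 300.0)
        rec = low.heights + high.heights
        rel = np.sqrt(np.mean((rec - control_texture.heights) ** 2)) \
            / np.sqrt(np.mean(control_texture.heights**2))
        assert rel < 1e-9

    def test_band_isolation_two_sinusoids(self):
        # grid-periodic wavevectors near the 939 / 98.5 nm scales (no leakage)
        n, pixel = 512, 10.0
        y, x = np.mgrid[0:n, 0:n].astype(float)
        s1 = 2.0 * np.sin(2 * np.pi * (5 * x + 2 * y) / n)      # ~951 nm
        s2 = 0.5 * np.sin(2 * np.pi * (42 * x + 31 * y) / n)    # ~98 nm
        hm = HeightMap(s1 + s2, pixel)
        low, high = decompose_bands(hm, 300.0)
        leak_low = np.sqrt(np.mean((low.heights - s1) ** 2)) / np.sqrt(np.mean(s1**2))
        leak_high = np.sqrt(np.mean((high.heights - s2) ** 2)) / np.sqrt(np.mean(s2**2))
        assert leak_low < 0.02 and leak_high < 0.02

    def test_flat_map_both_bands_flat(self):
        low, high = decompose_bands(HeightMap(np.zeros((128, 128)), 10.0), 300.0)
        assert np.all(low.heights == 0.0) and np.all(high.heights == 0.0)

    def test_cutoff_bounds(self):
        hm = HeightMap(np.zeros((128, 128)), 10.0)
        with pytest.raises(ValueError):
            decompose_bands(hm, 15.0)      # below 2 px
        with pytest.raises(ValueError):
            decompose_bands(hm, 5000.0)    # above field

    def test_frequency_filter_equals_spatial_convolution(self):
        # independent spatial-domain oracle for the low-pass filter
        from scipy import ndimage
        z = np.random.default_rng(2).normal(0, 1, (64, 64))
        hm = HeightMap(z, 10.0)
        mask = _lowpass_mask((64, 64), 10.0, 300.0)
        kernel = np.fft.fftshift(np.real(np.fft.ifft2(mask)))
        oracle = ndimage.convolve(z, kernel, mode="wrap")
        low, _ = decompose_bands(hm, 300.0)
        assert np.sqrt(np.mean((oracle - low.heights) ** 2)) < 1e-6


class TestBandParams:
    def test_sinusoid_closed_form(self):
        # peak-to-valley 2a -> h = 2a; L = period within one frequency bin
        hm = sinusoid_map(200.0, amplitude=1.5)
        h, L = band_params(hm)
        assert h == pytest.approx(3.0, rel=0.02)
        f = 1.0 / L
        assert f == pytest.approx(1.0 / 200.0, abs=1.0 / (256 * 10.0))

    def test_zero_map_sentinel(self):
        h, L = band_params(HeightMap(np.zeros((64, 64)), 10.0))
        assert h == 0.0 and np.isnan(L)

    def test_control_preset_recovery(self):
        res = []
        for s in range(1, 11):
            m = make_surface_texture(presets.TEXTURE_PRESETS["control"], seed=s)
            sp = surface_params(m)
            res.append([sp.h1, sp.L1, sp.h2, sp.L2])
        mean = np.mean(res, axis=0)
        target = np.array([2.7, 939.0, 0.9, 98.5])
        np.testing.assert_allclose(mean, target, rtol=0.10)


class TestSurfaceParams:
    def test_flat_map_zero_amplitudes(self):
        sp = surface_params(HeightMap(np.zeros((128, 128)), 10.0))
        assert sp.h1 == 0.0 and sp.h2 == 0.0
        assert np.isnan(sp.L1) and np.isnan(sp.L2)

    def test_acid_storage_preset_fold_changes(self):
        # pH 6.4 / 7 h: h1 x5, h2 x3.3, L1 x1.5, L2 x2 relative to control;
        # coarser sampling keeps the longer waviness period resolvable
        ratios = []
        for s in range(1, 6):
            c = surface_params(make_surface_texture(
                presets.TEXTURE_PRESETS["control"], pixel_size=15.0, seed=s))
            a = surface_params(make_surface_texture(
                presets.TEXTURE_PRESETS["ph64_7h"], pixel_size=15.0, seed=s))
            ratios.append([a.h1 / c.h1, a.L1 / c.L1, a.h2 / c.h2, a.L2 / c.L2])
        mean = np.mean(ratios, axis=0)
        np.testing.assert_allclose(mean, [5.0, 1.5, 3.3, 2.0], rtol=0.15)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_height_scaling_property(self, c, control_texture):
        # scaling heights by c scales h1, h2 by c and leaves L1, L2 unchanged
        sp0 = surface_params(control_texture)
        scaled = HeightMap(control_texture.heights * c, control_texture.pixel_size)
        sp = surface_params(scaled)
        assert sp.h1 == pytest.approx(c * sp0.h1, rel=1e-9)
        assert sp.h2 == pytest.approx(c * sp0.h2, rel=1e-9)
        assert sp.L1 == pytest.approx(sp0.L1, rel=1e-12)
        assert sp.L2 == pytest.approx(sp0.L2, rel=1e-12)
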