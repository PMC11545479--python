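"""Fourier surface metrology: waviness/roughness decomposition of AFM maps.

A flattened height map is split in the frequency domain into a
low-frequency *waviness* band and a high-frequency *roughness* band with a
complementary raised-cosine filter around a cutoff wavelength.  Each band
is summarized by an amplitude h = 2*sqrt(2)*RMS (the peak-to-valley of the
RMS-equivalent sinusoid) and a dominant lateral period L taken from the
power-weighted mode of the band's radially averaged power spectrum.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io import HeightMap, InsufficientDataError
from .synthetic.surface import AMPLITUDE_FACTOR

DEFAULT_CUTOFF_NM = 300.0  # geometric midpoint between the ~100 nm and ~900 nm scales
TRANSITION_WIDTH = 0.2     # relative width of the raised-cosine band edge


@dataclasses.dataclass(frozen=True)
class SurfaceParams:
    """Waviness (h1, L1) and roughness (h2, L2) parameters in nm.

    L is NaN (undefined sentinel) when the corresponding band carries no
    power.
    """

    h1: float
    L1: float
    h2: float
    L2: float


@dataclasses.dataclass(frozen=True)
class RadialPSD:
    """Azimuthally averaged power spectral density.

    ``power`` is the mean 2-D spectral density (nm^2 per unit frequency
    squared) over the annulus at each ``spatial_frequency`` (1/nm, strictly
    increasing, DC excluded), so a white-noise map has a flat profile.
    ``counts`` holds the number of 2-D frequency bins per annulus;
    ``total_power()`` performs the annulus-weighted Parseval sum, which
    recovers the map variance.
    """

    spatial_frequency: np.ndarray
    power: np.ndarray
    counts: np.ndarray
    bin_width: float

    def total_power(self) -> float:
        return float(np.sum(self.power * self.counts) * self.bin_width**2)


def flatten(hmap: HeightMap, order: int = 2) -> HeightMap:
    """Subtract a least-squares 2-D polynomial background of given degree.

    Degree 1 removes sample tilt, 2-3 remove cell-body curvature.  The
    residual has (numerically) zero mean.
    """
    if order not in (1, 2, 3):
        raise ValueError("flatten order must be 1, 2 or 3")
    z = hmap.heights
    n_terms = (order + 1) * (order + 2) // 2
    if z.size < n_terms:
        raise InsufficientDataError("map smaller than number of polynomial terms")
    ny, nx = z.shape
    # normalized coordinates keep the design matrix well-conditioned
    y, x = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    cols = [x.ravel() ** i * y.ravel() ** j
            for i in range(order + 1) for j in range(order + 1 - i)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    residual = z.ravel() - A @ coef
    return HeightMap(residual.reshape(z.shape), hmap.pixel_size, name=hmap.name)


def _pad_square(z: np.ndarray) -> np.ndarray:
    n = max(z.shape)
    if z.shape == (n, n):
        return z
    out = np.zeros((n, n))
    out[: z.shape[0], : z.shape[1]] = z
    return out


def radial_psd(hmap: HeightMap) -> RadialPSD:
    """Hann-windowed 2-D power spectrum averaged over annuli of constant |f|.

    Normalized so that total power (sum of density times bin width) equals
    the map variance up to windowing error; non-square maps are zero-padded
    to square.
    """
    z = hmap.heights
    if min(z.shape) <= 8:
        raise InsufficientDataError("map too small for a meaningful spectrum")
    z = _pad_square(z - z.mean())
    n = z.shape[0]
    w = np.hanning(n)[:, None] * np.hanning(n)[None, :]
    F = np.fft.fft2(z * w)
    power2d = np.abs(F) ** 2 / (z.size * np.sum(w**2))   # sums to windowed variance
    f = np.fft.fftfreq(n, d=hmap.pixel_size)
    fr = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    df = 1.0 / (n * hmap.pixel_size)
    idx = np.rint(fr / df).astype(int)             # annulus index; 0 = DC
    n_bins = idx.max() + 1
    sums = np.bincount(idx.ravel(), weights=power2d.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    freqs = np.arange(1, n_bins) * df
    density = sums[1:] / np.maximum(counts[1:], 1) / df**2
    return RadialPSD(freqs, density, counts[1:], df)


def _lowpass_mask(shape: tuple[int, int], pixel_size: float, cutoff_nm: float,
                  transition: float = TRANSITION_WIDTH) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    fc = 1.0 / cutoff_nm
    lo, hi = fc * (1.0 - transition / 2.0), fc * (1.0 + transition / 2.0)
    mask = np.clip((hi - fr) / (hi - lo), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * mask)        # raised cosine in [0, 1]


def decompose_bands(hmap: HeightMap, cutoff_nm: float = DEFAULT_CUTOFF_NM
                    ) -> tuple[HeightMap, HeightMap]:
    """Split a map into (waviness, roughness) with exact reconstruction.

    The frequency-domain filter is a complementary raised cosine of
    relative width 0.2 around the cutoff; low + high == input to machine
    precision because the high band is computed as the residual.
    """
    field = min(hmap.shape) * hmap.pixel_size
    if not (2.0 * hmap.pixel_size < cutoff_nm < field):
        raise ValueError(
            f"cutoff {cutoff_nm} nm outside resolvable range "
            f"({2 * hmap.pixel_size:.3g}, {field:.3g}) nm")
    z = hmap.heights
    mask = _lowpass_mask(z.shape, hmap.pixel_size, cutoff_nm)
    low = np.real(np.fft.ifft2(np.fft.fft2(z) * mask))
    return (HeightMap(low, hmap.pixel_size, name=hmap.name + ":low"),
            HeightMap(z - low, hmap.pixel_size, name=hmap.name + ":high"))


def band_params(band: HeightMap) -> tuple[float, float]:
    """Amplitude h (nm) and dominant period L (nm) of a band-filtered map.

    h = 2*sqrt(2)*RMS about the mean; L = 1/f_peak with f_peak the
    parabolically interpolated maximum of the radial PSD.  A zero-power
    band yields (0, NaN).
    """
    z = band.heights
    rms = float(np.std(z))
    h = AMPLITUDE_FACTOR * rms
    if rms < 1e-12:
        return 0.0, math.nan
    psd = radial_psd(band)
    p = psd.power
    i = int(np.argmax(p))
    if 0 < i < len(p) - 1 and p[i - 1] != p[i + 1]:
        denom = p[i - 1] - 2.0 * p[i] + p[i + 1]
        shift = 0.5 * (p[i - 1] - p[i + 1]) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    f_peak = psd.spatial_frequency[i] + shift * psd.bin_width
    return h, float(1.0 / f_peak)


def surface_params(hmap: HeightMap, cutoff_nm: float = DEFAULT_CUTOFF_NM,
                   flatten_order: int = 2) -> SurfaceParams:
    """Full metrology chain: flatten, band-split, summarize each band."""
    flat = flatten(hmap, order=flatten_order)
    low, high = decompose_bands(flat, cutoff_nm=cutoff_nm)
    h1, L1 = band_params(low)
    h2, L2 = band_params(high)
    return SurfaceParams(h1=h1, L1=L1, h2=h2, L2=L2)
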