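"""Banded random surface textures emulating the RBC membrane nanostructure.

A membrane patch is modelled as the sum of two isotropic sinusoid
ensembles: a *waviness* band (amplitude h1, lateral period L1) and a
*roughness* band (h2, L2).  The amplitude convention is shared with the
metrology module: h is the peak-to-valley amplitude of the equivalent
single sinusoid, i.e. h = 2*sqrt(2) * RMS of the band, and L is the
dominant radial wavelength of the band's power spectrum.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..io import HeightMap

AMPLITUDE_FACTOR = 2.0 * np.sqrt(2.0)  # peak-to-valley of the RMS-equivalent sinusoid


@dataclasses.dataclass(frozen=True)
class TextureParams:
    """Ground-truth surface texture parameters (all lengths in nm)."""

    h1: float
    L1: float
    h2: float
    L2: float
    n_components: int = 12

    def __post_init__(self) -> None:
        if self.h1 < 0 or self.h2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (self.L1 > self.L2 > 0):
            raise ValueError("periods must satisfy L1 > L2 > 0")
        if self.n_components < 1:
            raise ValueError("need at least one sinusoid per band")


def _ring_wavevectors(n: int, radius: float) -> np.ndarray:
    """Integer wavevectors (half-plane) with |k| nearest to `radius` grid units.

    Grid-periodic wavevectors keep each sinusoid leakage-free on the FFT
    grid, so band energies separate exactly at analysis time.  The ring
    tolerance widens until at least ``n`` distinct vectors are available.
    """
    kmax = int(np.ceil(radius)) + 2
    kx, ky = np.meshgrid(np.arange(-kmax, kmax + 1), np.arange(-kmax, kmax + 1))
    half = (kx > 0) | ((kx == 0) & (ky > 0))       # one of each +/-k pair
    kr = np.sqrt(kx**2 + ky**2)
    for tol in (0.5, 0.75, 1.0, 1.5, 2.0):
        sel = half & (np.abs(kr - radius) <= tol)
        if sel.sum() >= n:
            break
    vecs = np.column_stack([ky[sel], kx[sel]])
    # prefer vectors closest to the target ring
    order = np.argsort(np.abs(np.sqrt((vecs**2).sum(1)) - radius), kind="stable")
    return vecs[order]


def _sinusoid_band(shape: tuple[int, int], pixel_size: float, h: float, L: float,
                   n_components: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of n random-orientation grid-periodic sinusoids, band RMS h/(2*sqrt(2))."""
    ny, nx = shape
    n_grid = max(ny, nx)
    radius = n_grid * pixel_size / L               # target |k| in grid units
    candidates = _ring_wavevectors(n_components, radius)
    take = min(n_components, len(candidates))
    idx = rng.permutation(len(candidates))[:take]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    target_rms = h / AMPLITUDE_FACTOR
    # n distinct equal-amplitude sinusoids: n * a^2 / 2 = rms^2 exactly
    a = target_rms * np.sqrt(2.0 / take)
    band = np.zeros(shape)
    for ky, kx in candidates[idx]:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        band += a * np.sin(2.0 * np.pi * (kx * xx + ky * yy) / n_grid + phase)
    return band


def make_surface_texture(params: TextureParams, size: int = 512,
                         pixel_size: float = 10.0,
                         seed: int | np.random.Generator | None = 0,
                         name: str = "texture") -> HeightMap:
    """Generate a two-band sinusoid-ensemble texture map.

    Parameters
    ----------
    params
        Ground-truth (h1, L1, h2, L2) and components per band.
    size
        Map edge length in pixels (square map), >= 128.
    pixel_size
        nm per pixel; both periods must be resolvable:
        4*pixel_size <= L <= size*pixel_size/4.
    seed
        Seed or Generator; the map is deterministic given it.
    """
    if size < 128:
        raise ValueError("size must be >= 128 pixels")
    field = size * pixel_size
    for L, h in ((params.L1, params.h1), (params.L2, params.h2)):
        if h > 0 and not (4.0 * pixel_size <= L <= field / 4.0):
            raise ValueError(
                f"period {L} nm unresolvable on {size} px grid at {pixel_size} nm/px")
    rng = np.random.default_rng(seed)
    z = np.zeros((size, size))
    if params.h1 > 0:
        z += _sinusoid_band((size, size), pixel_size, params.h1, params.L1,
                            params.n_components, rng)
    if params.h2 > 0:
        z += _sinusoid_band((size, size), pixel_size, params.h2, params.L2,
                            params.n_components, rng)
    return HeightMap(z, pixel_size, name=name)
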