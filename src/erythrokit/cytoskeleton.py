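"""Watershed segmentation of cytoskeletal pores and pore statistics.

Pores are depressions enclosed by filament ridges in a high-resolution
mesh image.  Markers are regional minima deeper than a threshold below the
surrounding relief (h-minima transform); the watershed then floods the
height relief within a mask that excludes the filament crests, so each
detected pore is the depressed interior, not the whole basin up to the
ridge line.  Border-touching pores are excluded from counts and lengths;
the count is rescaled with a guard-zone correction for the excluded border
band.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage
from skimage.morphology import h_minima
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io import HeightMap
from .synthetic.mesh import REFERENCE_WINDOW_UM2


@dataclasses.dataclass(frozen=True)
class PoreSet:
    """Labelled pores of one field: 0 = filament/background."""

    labels: np.ndarray          # 2-D int
    areas_um2: np.ndarray       # per interior pore
    feret_um: np.ndarray        # per interior pore, max Feret
    field_area_um2: float
    pixel_size: float           # nm/px

    @property
    def count(self) -> int:
        return int(len(self.areas_um2))


@dataclasses.dataclass(frozen=True)
class PoreStats:
    count_per_window: float     # pores per 2x2 um^2
    mean_feret_um: float
    sd_feret_um: float
    n_pores: int
    empty: bool = False


def feret_max(mask: np.ndarray, pixel_size: float) -> float:
    """Maximum Feret diameter of a pixel mask in um.

    Distances are between pixel centres; the convex hull reduces the
    all-pairs search, falling back to brute force for tiny or degenerate
    (collinear) masks.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask")
    pts = np.column_stack([ys, xs]).astype(float)
    if len(pts) >= 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass                                    # collinear: brute force below
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()) * pixel_size / 1000.0)


def detect_pores(hmap: HeightMap, smooth_sigma: float = 10.0,
                 depth_threshold: float = 0.5, min_area_um2: float = 1e-4,
                 mask_level: float = 0.5,
                 marker_merge_factor: float = 3.0) -> PoreSet:
    """Segment pores from a mesh height map.

    Parameters (all config-exposed):
    smooth_sigma -- Gaussian pre-smoothing, nm.
    depth_threshold -- minimum depth (nm) of a regional minimum below its
        surroundings to seed a pore.
    min_area_um2 -- discard components smaller than this.
    mask_level -- flood mask cut as a fraction of the floor-to-crest relief;
        0.5 places pore boundaries at the half-height of the filament walls.
    marker_merge_factor -- minima closer than this multiple of smooth_sigma
        are merged into one marker (suppresses over-segmentation).
    """
    z = hmap.heights.astype(float)
    sigma_px = smooth_sigma / hmap.pixel_size
    zs = ndimage.gaussian_filter(z, sigma=sigma_px, mode="nearest")
    floor, crest = np.percentile(zs, [2.0, 98.0])
    relief = crest - floor
    px_um2 = (hmap.pixel_size / 1000.0) ** 2
    field_area = z.size * px_um2
    if relief <= depth_threshold:
        return PoreSet(np.zeros(z.shape, int), np.array([]), np.array([]),
                       field_area, hmap.pixel_size)

    minima = h_minima(zs, depth_threshold)
    if marker_merge_factor > 0:
        merge_px = max(int(round(marker_merge_factor * sigma_px)), 1)
        minima = ndimage.binary_dilation(minima, ndimage.generate_binary_structure(2, 2),
                                         iterations=merge_px)
    markers, n_markers = ndimage.label(minima)
    if n_markers == 0:
        return PoreSet(np.zeros(z.shape, int), np.array([]), np.array([]),
                       field_area, hmap.pixel_size)
    flood_mask = zs < floor + mask_level * relief
    labels = watershed(zs, markers=markers, mask=flood_mask)

    ny, nx = z.shape
    areas, ferets, keep = [], [], []
    for rp in regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        if minr == 0 or minc == 0 or maxr == ny or maxc == nx:
            continue                                # border-touching: excluded
        if rp.area * px_um2 < min_area_um2:
            continue
        keep.append(rp.label)
        areas.append(rp.area * px_um2)
        mask = labels == rp.label
        ferets.append(feret_max(mask, hmap.pixel_size))
    out_labels = np.where(np.isin(labels, keep), labels, 0)
    return PoreSet(out_labels, np.asarray(areas), np.asarray(ferets),
                   field_area, hmap.pixel_size)


def pore_stats(pores: PoreSet) -> PoreStats:
    """Count density (per 2x2 um^2) and Feret statistics.

    The density uses a guard-zone correction: pores are counted only if
    fully interior, so the effective sampling window is the field eroded
    by the mean pore radius on every side.
    """
    if pores.count == 0:
        return PoreStats(0.0, 0.0, 0.0, 0, empty=True)
    side_um = np.sqrt(pores.field_area_um2)
    r_mean = float(np.mean(np.sqrt(pores.areas_um2 / np.pi)))
    eff_side = max(side_um - 2.0 * r_mean, side_um / 2.0)
    density = pores.count / eff_side**2 * REFERENCE_WINDOW_UM2
    return PoreStats(count_per_window=float(density),
                     mean_feret_um=float(np.mean(pores.feret_um)),
                     sd_feret_um=float(np.std(pores.feret_um, ddof=1)) if pores.count > 1 else 0.0,
                     n_pores=pores.count)
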