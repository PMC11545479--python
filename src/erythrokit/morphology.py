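"""Cell segmentation and shape classification of scene height maps.

Cells are segmented as connected components above a substrate threshold;
each cell is reduced to a normalized radial height profile plus an angular
rim series, from which simple geometric indices separate the three shape
classes:

* echinocyte — >= ``spicule_min`` prominent angular maxima on the rim;
* codocyte — central height exceeds the mid-radius minimum by more than
  ``dome_threshold`` of the cell height (central dome inside a trough);
* discocyte — rim maximum exceeds the centre by more than
  ``dimple_threshold`` of the cell height (biconcave dimple);
* anything else — unclassified.

The indices are normalized by cell height, so classification is invariant
to uniform height scaling, and the radial reduction makes it invariant to
translation and 90-degree rotation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.measure import label as sk_label, regionprops

from .io import HeightMap, InsufficientDataError
from .synthetic.cells import CellComposition


@dataclasses.dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds; defaults separate the parametric archetypes with margin."""

    spicule_min: int = 6
    dimple_threshold: float = 0.05
    dome_threshold: float = 0.05
    prominence_factor: float = 2.0
    min_rim_relative_rms: float = 0.02   # below this the rim counts as smooth
    mid_band: tuple[float, float] = (0.25, 0.8)


@dataclasses.dataclass(frozen=True)
class CellRegion:
    """A segmented cell: mask footprint and basic geometry."""

    mask: np.ndarray            # boolean, full-scene shape
    centroid: tuple[float, float]   # px (row, col)
    equivalent_diameter_um: float
    mean_height_nm: float
    max_radius_px: float


@dataclasses.dataclass(frozen=True)
class CellClassification:
    label: str                  # discocyte | echinocyte | codocyte | unclassified
    dimple_index: float
    spicule_count: int
    center_dome_index: float


def segment_cells(scene: HeightMap, min_height: float = 200.0,
                  area_bounds_um2: tuple[float, float] = (10.0, 80.0)
                  ) -> list[CellRegion]:
    """Connected components above ``min_height`` nm, border and size filtered."""
    binary = scene.heights > min_height
    labels = sk_label(binary, connectivity=2)
    px_um2 = (scene.pixel_size / 1000.0) ** 2
    regions = []
    ny, nx = scene.shape
    for rp in regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        if minr == 0 or minc == 0 or maxr == ny or maxc == nx:
            continue                                # border-touching
        area_um2 = rp.area * px_um2
        if not (area_bounds_um2[0] <= area_um2 <= area_bounds_um2[1]):
            continue
        mask = labels == rp.label
        cy, cx = rp.centroid
        ys, xs = np.nonzero(mask)
        max_r = float(np.sqrt(((ys - cy) ** 2 + (xs - cx) ** 2).max()))
        regions.append(CellRegion(
            mask=mask, centroid=(cy, cx),
            equivalent_diameter_um=2.0 * np.sqrt(area_um2 / np.pi),
            mean_height_nm=float(scene.heights[mask].mean()),
            max_radius_px=max_r))
    return regions


def radial_profile(scene: HeightMap, cell: CellRegion, n_bins: int = 24,
                   n_angular: int = 90, rim_radius_frac: float = 0.8
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mean height vs normalized radius, plus the angular rim series.

    The radial profile averages heights over annuli of r/R in [0, 1] with
    R the maximum mask radius; the angular series samples the surface at
    r = rim_radius_frac * R by bilinear interpolation.
    """
    cy, cx = cell.centroid
    R = cell.max_radius_px
    if R < n_bins:
        raise InsufficientDataError("cell smaller than the requested radial binning")
    ys, xs = np.nonzero(cell.mask)
    r_norm = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2) / R
    bins = np.clip((r_norm * n_bins).astype(int), 0, n_bins - 1)
    heights = scene.heights[ys, xs]
    sums = np.bincount(bins, weights=heights, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    angles = np.linspace(0.0, 2.0 * np.pi, n_angular, endpoint=False)
    rr = cy + rim_radius_frac * R * np.sin(angles)
    cc = cx + rim_radius_frac * R * np.cos(angles)
    angular = ndimage.map_coordinates(scene.heights, np.vstack([rr, cc]), order=1)
    return profile, angular


def _count_spicules(angular: np.ndarray, cell_height: float,
                    th: ClassifierThresholds) -> int:
    a = angular - angular.mean()
    rms = float(np.std(a))
    if cell_height <= 0 or rms < th.min_rim_relative_rms * cell_height:
        return 0
    tiled = np.tile(a, 3)
    peaks, _ = find_peaks(tiled, prominence=th.prominence_factor * rms)
    n = len(angular)
    in_middle = peaks[(peaks >= n) & (peaks < 2 * n)]
    return int(len(in_middle))


def classify_cell(profile: np.ndarray, angular: np.ndarray,
                  thresholds: ClassifierThresholds | None = None) -> CellClassification:
    """Apply the spicule / dome / dimple decision rule to one cell."""
    th = thresholds or ClassifierThresholds()
    profile = np.asarray(profile, dtype=float)
    height = float(profile.max() - profile.min())
    if height <= 0:
        return CellClassification("unclassified", 0.0, 0, 0.0)
    n = len(profile)
    lo, hi = int(th.mid_band[0] * n), max(int(th.mid_band[1] * n), int(th.mid_band[0] * n) + 1)
    mid_min = float(profile[lo:hi].min())
    center = float(profile[0])
    dome_index = (center - mid_min) / height
    dimple_index = (float(profile.max()) - center) / height
    spicules = _count_spicules(np.asarray(angular, dtype=float), height, th)

    if spicules >= th.spicule_min:
        label = "echinocyte"
    elif dome_index > th.dome_threshold:
        label = "codocyte"
    elif dimple_index > th.dimple_threshold:
        label = "discocyte"
    else:
        label = "unclassified"
    return CellClassification(label, dimple_index, spicules, dome_index)


def scene_composition(scene: HeightMap,
                      min_height: float = 200.0,
                      thresholds: ClassifierThresholds | None = None
                      ) -> tuple[CellComposition, pd.DataFrame]:
    """Segment, profile and classify every cell; report class percentages.

    Percentages are taken over classified cells; unclassified cells appear
    in the per-cell table but not in the composition.
    """
    cells = segment_cells(scene, min_height=min_height)
    if not cells:
        raise ValueError("no cells segmented from the scene")
    rows = []
    for i, cell in enumerate(cells):
        try:
            profile, angular = radial_profile(scene, cell)
        except InsufficientDataError:
            rows.append({"cell": i, "label": "unclassified", "dimple_index": np.nan,
                         "spicule_count": 0, "center_dome_index": np.nan,
                         "equivalent_diameter_um": cell.equivalent_diameter_um})
            continue
        cls = classify_cell(profile, angular, thresholds)
        rows.append({"cell": i, "label": cls.label,
                     "dimple_index": cls.dimple_index,
                     "spicule_count": cls.spicule_count,
                     "center_dome_index": cls.center_dome_index,
                     "equivalent_diameter_um": cell.equivalent_diameter_um})
    table = pd.DataFrame(rows)
    classified = table[table["label"] != "unclassified"]
    if len(classified) == 0:
        raise ValueError("no cells could be classified")
    pct = classified["label"].value_counts(normalize=True) * 100.0
    comp = CellComposition(discocyte=float(pct.get("discocyte", 0.0)),
                           echinocyte=float(pct.get("echinocyte", 0.0)),
                           codocyte=float(pct.get("codocyte", 0.0)))
    return comp, table
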