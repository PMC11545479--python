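"""Synthetic spectrin-actin mesh images: filament ridges enclosing pores.

The network geometry is a Voronoi tessellation of Poisson-distributed seed
points.  Each Voronoi cell, shrunk about its centroid, becomes a pore
(depression); the remaining band along the tessellation edges is the
elevated filament.  The Poisson intensity is set by ``pore_density``; the
global shrink factor is calibrated so the ground-truth mean maximum-Feret
pore length matches ``mean_pore_length``.  Ground truth (per-pore area and
Feret length) comes from the exact polygons, independent of rasterization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
import shapely
from shapely.geometry import Polygon, box
from shapely.affinity import scale as shp_scale
from skimage.draw import polygon as draw_polygon

from ..io import HeightMap

REFERENCE_WINDOW_UM2 = 4.0  # pore densities are quoted per 2x2 um^2


@dataclasses.dataclass(frozen=True)
class MeshParams:
    """Ground-truth mesh parameters.

    pore_density : pores per 2x2 um^2 reference window
    mean_pore_length : target mean max-Feret pore length, um
    ridge_width : minimum filament width, nm
    """

    pore_density: float
    mean_pore_length: float
    ridge_width: float = 30.0

    def __post_init__(self) -> None:
        if self.pore_density <= 0:
            raise ValueError("pore_density must be positive")
        if self.mean_pore_length <= 0:
            raise ValueError("mean_pore_length must be positive")
        if self.ridge_width <= 0:
            raise ValueError("ridge_width must be positive")


@dataclasses.dataclass(frozen=True)
class GroundTruthPore:
    """One generated pore: area (um^2), max Feret (um), centroid (nm)."""

    area_um2: float
    feret_um: float
    centroid_nm: tuple[float, float]


def polygon_feret(poly: Polygon) -> float:
    """Maximum caliper (Feret) diameter of a convex-ish polygon, same units."""
    pts = np.asarray(poly.convex_hull.exterior.coords)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _voronoi_cells(points: np.ndarray, field: float) -> list[Polygon]:
    """Bounded Voronoi cells of `points` inside [0, field]^2 (nm units).

    Cells at the boundary are closed by mirroring the point set across the
    four field edges, then clipped to the field box.
    """
    mirrored = [points]
    for axis in (0, 1):
        for edge in (0.0, field):
            m = points.copy()
            m[:, axis] = 2.0 * edge - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    clip = box(0.0, 0.0, field, field)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(clip)
        cells.append(poly)
    return cells


def make_cytoskeleton_image(params: MeshParams, size: int = 1024,
                            pixel_size: float | None = None,
                            field_um: float = 2.0,
                            seed: int | np.random.Generator | None = 0,
                            ridge_height: float = 20.0,
                            noise_sd: float = 0.1,
                            seed_points_nm: np.ndarray | None = None,
                            name: str = "mesh") -> tuple[HeightMap, list[GroundTruthPore]]:
    """Generate a mesh height map plus exact ground-truth pore list.

    Parameters
    ----------
    params
        Pore density / target pore length / minimum filament width.
    size, pixel_size, field_um
        Square field geometry; if ``pixel_size`` is omitted it is
        ``field_um * 1000 / size`` nm/px.
    ridge_height
        Filament elevation above the pore floor, nm.
    seed_points_nm
        Optional explicit seed points (nm coordinates), overriding the
        Poisson draw — used for deterministic tessellation fixtures.

    Ground truth contains every pore polygon fully inside the field
    (border-clipped cells contribute filament mass but are not listed,
    mirroring the analysis convention of excluding border pores).
    """
    rng = np.random.default_rng(seed)
    if pixel_size is None:
        pixel_size = field_um * 1000.0 / size
    field = size * pixel_size                      # nm
    area_um2 = (field / 1000.0) ** 2
    expected = params.pore_density * area_um2 / REFERENCE_WINDOW_UM2
    if seed_points_nm is None:
        if expected < 4:
            raise ValueError("expected pore count on the field must be >= 4")
        n = max(int(rng.poisson(expected)), 4)
        points = rng.uniform(0.0, field, size=(n, 2))
    else:
        points = np.asarray(seed_points_nm, dtype=float)
        if len(points) < 4:
            raise ValueError("need at least 4 seed points")
    spacing = field / np.sqrt(len(points))
    if params.ridge_width >= spacing:
        raise ValueError(
            f"ridge_width {params.ridge_width} nm >= typical pore spacing {spacing:.0f} nm")

    cells = _voronoi_cells(points, field)
    boundary = box(0.0, 0.0, field, field).exterior
    interior = [c for c in cells if not c.intersects(boundary) and c.area > 0]
    if not interior:
        # tiny deterministic tessellations: calibrate on the clipped cells
        interior = [c for c in cells if c.area > 0]

    # calibrate the global shrink factor so interior mean Feret hits the target
    target_nm = params.mean_pore_length * 1000.0
    factor = 1.0
    for _ in range(3):
        ferets = [polygon_feret(shp_scale(c, factor, factor, origin="centroid"))
                  for c in interior]
        mean_f = float(np.mean(ferets))
        if mean_f <= 0:
            break
        factor *= target_nm / mean_f
    factor = min(factor, 0.95)  # pores never exceed their tessellation cell

    pores: list[Polygon] = []
    for c in cells:
        p = shp_scale(c, factor, factor, origin="centroid")
        # enforce the minimum filament width along tessellation edges
        p = p.intersection(c.buffer(-params.ridge_width / 2.0))
        if not p.is_empty and p.geom_type == "Polygon" and p.area > 0:
            pores.append(p)

    # rasterize: filament everywhere, pore interiors at floor level
    z = np.full((size, size), ridge_height)
    for p in pores:
        coords = np.asarray(p.exterior.coords) / pixel_size
        rr, cc = draw_polygon(coords[:, 1], coords[:, 0], shape=z.shape)
        z[rr, cc] = 0.0
    z = gaussian_filter(z, sigma=1.5, mode="nearest")
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, z.shape)

    truth = []
    for p in pores:
        if p.intersects(boundary):
            continue
        cy, cx = p.centroid.y, p.centroid.x
        truth.append(GroundTruthPore(area_um2=p.area / 1e6,
                                     feret_um=polygon_feret(p) / 1000.0,
                                     centroid_nm=(cy, cx)))
    return HeightMap(z, pixel_size, name=name), truth
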