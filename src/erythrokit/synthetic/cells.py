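"""Parametric cell-scene generator: discocytes, echinocytes, codocytes.

Each cell is a radial height model on a flat substrate:

* discocyte — biconcave disc: elevated rim, central dimple (centre height
  about half the rim height);
* echinocyte — dome with >= 10 short radial spicules, rendered as a
  sharpened angular sinusoid concentrated at the rim;
* codocyte ("target cell") — annular trough with a central dome inside
  the rim.

Sizes follow textbook RBC geometry (default 7.5 um diameter, ~1.2 um rim
height on the substrate) with per-cell lognormal-ish jitter; cells are
placed without overlap by rejection sampling.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..io import HeightMap

LABELS = ("discocyte", "echinocyte", "codocyte")


@dataclasses.dataclass(frozen=True)
class CellComposition:
    """Scene composition as percentages per shape class (sum to 100)."""

    discocyte: float
    echinocyte: float
    codocyte: float

    def __post_init__(self) -> None:
        for v in (self.discocyte, self.echinocyte, self.codocyte):
            if not (0.0 <= v <= 100.0):
                raise ValueError("fractions must be within [0, 100]")
        if abs(self.discocyte + self.echinocyte + self.codocyte - 100.0) > 1e-6:
            raise ValueError("fractions must sum to 100")

    def as_dict(self) -> dict[str, float]:
        return {"discocyte": self.discocyte, "echinocyte": self.echinocyte,
                "codocyte": self.codocyte}


@dataclasses.dataclass(frozen=True)
class CellGroundTruth:
    """Per-cell generator record: class label, centre (px) and radius (nm)."""

    label: str
    center: tuple[float, float]
    radius_nm: float
    rim_height_nm: float


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


def largest_remainder_counts(comp: CellComposition, n: int) -> dict[str, int]:
    """Integer class counts from percentages by largest-remainder rounding."""
    quotas = {lab: comp.as_dict()[lab] * n / 100.0 for lab in LABELS}
    counts = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    short = n - sum(counts.values())
    for lab in sorted(LABELS, key=lambda l: quotas[l] - counts[l], reverse=True)[:short]:
        counts[lab] += 1
    return counts


def _cell_height_field(label: str, rho: np.ndarray, theta: np.ndarray,
                       rim_h: float, n_spicules: int, spicule_phase: float) -> np.ndarray:
    """Height of one cell at normalized radius rho (0..1) and angle theta."""
    rho = np.clip(rho, 0.0, 1.0)
    ring = 4.0 * rho**2 * (1.0 - rho**2)          # 0 at centre/edge, 1 at rho=1/sqrt(2)
    if label == "discocyte":
        # rim ring plus a half-height central mound -> biconcave profile
        return rim_h * ring + 0.5 * rim_h * (1.0 - rho**2) ** 3
    if label == "echinocyte":
        dome = rim_h * (1.0 - rho**2) ** 0.7
        spic = (0.5 + 0.5 * np.cos(n_spicules * theta + spicule_phase)) ** 3
        return dome + 0.5 * rim_h * ring * spic
    if label == "codocyte":
        dome = 0.8 * rim_h * np.clip(1.0 - (rho / 0.45) ** 2, 0.0, None) ** 2
        return rim_h * ring + dome
    raise ValueError(f"unknown cell class {label!r}")


def make_cell_scene(comp: CellComposition, n_cells: int,
                    seed: int | np.random.Generator | None = 0,
                    pixel_size: float | None = None,
                    field_px: int = 1024,
                    mean_diameter_um: float = 7.5,
                    rim_height_nm: float = 1200.0,
                    size_jitter: float = 0.08,
                    max_tries: int = 20000,
                    name: str = "scene") -> tuple[HeightMap, list[CellGroundTruth]]:
    """Render a non-overlapping scene of n_cells and return ground-truth labels.

    The field of view is auto-sized (unless ``pixel_size`` is given) so the
    cells occupy ~30% of the area, which rejection sampling handles
    comfortably.  Class counts come from the composition percentages by
    largest-remainder rounding; placement order is shuffled so classes are
    spatially mixed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mean_r = mean_diameter_um * 1000.0 / 2.0                     # nm
    if pixel_size is None:
        field_nm = np.sqrt(n_cells * np.pi * mean_r**2 / 0.30)
        field_nm = max(field_nm, 4.0 * mean_r)
        pixel_size = field_nm / field_px
    field_nm = field_px * pixel_size

    counts = largest_remainder_counts(comp, n_cells)
    labels = [lab for lab in LABELS for _ in range(counts[lab])]
    rng.shuffle(labels)

    # rejection-sample non-overlapping centres, away from the border
    radii = mean_r * np.exp(rng.normal(0.0, size_jitter, size=n_cells))
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    margin = 2.0 * pixel_size
    for i in range(n_cells):
        r = radii[i]
        for attempt in range(max_tries):
            cy = rng.uniform(r + margin, field_nm - r - margin)
            cx = rng.uniform(r + margin, field_nm - r - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + margin) ** 2
                   for (py, px), pr in zip(centers, placed_r)):
                centers.append((cy, cx))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} without overlap; "
                "reduce n_cells or enlarge the field")

    z = np.zeros((field_px, field_px))
    truth: list[CellGroundTruth] = []
    for lab, (cy, cx), r in zip(labels, centers, placed_r):
        rim_h = rim_height_nm * float(np.exp(rng.normal(0.0, size_jitter)))
        n_spic = int(rng.integers(10, 17))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        # render on the local bounding box only
        i0 = max(int((cy - r) / pixel_size) - 1, 0)
        i1 = min(int((cy + r) / pixel_size) + 2, field_px)
        j0 = max(int((cx - r) / pixel_size) - 1, 0)
        j1 = min(int((cx + r) / pixel_size) + 2, field_px)
        yy = (np.arange(i0, i1) + 0.5) * pixel_size - cy
        xx = (np.arange(j0, j1) + 0.5) * pixel_size - cx
        dy, dx = np.meshgrid(yy, xx, indexing="ij")
        rho = np.sqrt(dy**2 + dx**2) / r
        theta = np.arctan2(dy, dx)
        patch = np.where(rho <= 1.0,
                         _cell_height_field(lab, rho, theta, rim_h, n_spic, phase),
                         0.0)
        z[i0:i1, j0:j1] = np.maximum(z[i0:i1, j0:j1], patch)
        truth.append(CellGroundTruth(lab, (cy / pixel_size, cx / pixel_size), r, rim_h))
    return HeightMap(z, pixel_size, name=name), truth
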