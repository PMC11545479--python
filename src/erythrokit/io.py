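"""Readers and writers for the on-disk formats used throughout the toolkit.

Height maps travel as a whitespace-delimited text matrix plus a JSON sidecar
(``<path>.json``) carrying the pixel size; every 1-D signal (force curve,
absorption spectrum, current trace) travels as a two-column delimited table.
Instrument-native formats (FemtoScan, Nova, pClamp) are out of scope; export
to text from the vendor software and load here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


class InsufficientDataError(ValueError):
    """Raised when an input is well-formed but too small to analyse."""


@dataclasses.dataclass(frozen=True)
class XYSeries:
    """An ordered 1-D signal: force curve, spectrum or current trace.

    ``x`` is strictly increasing, ``y`` has matching length and both are
    finite.  Units are carried as free-text labels (e.g. ``("nm", "nm")``
    for a force curve, ``("nm", "OD")`` for a spectrum, ``("s", "pA")``
    for an amperometric trace).
    """

    x: np.ndarray
    y: np.ndarray
    units: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise FormatError("x and y must be 1-D arrays of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise FormatError("non-finite values in series")
        if x.size >= 2 and not np.all(np.diff(x) > 0):
            raise FormatError("x must be strictly increasing")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclasses.dataclass(frozen=True)
class HeightMap:
    """A rectangular AFM height field in nm with isotropic pixel size (nm/px).

    Row 0 is the top of the image; heights are relative to the substrate
    plane at 0 nm.
    """

    heights: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if h.ndim != 2 or h.size == 0:
            raise FormatError("heights must be a non-empty 2-D array")
        if not np.isfinite(h).all():
            raise FormatError("non-finite heights")
        if not (self.pixel_size > 0):
            raise FormatError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def field_size(self) -> tuple[float, float]:
        """Physical extent (height, width) in nm."""
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_heightmap(path: str | Path) -> HeightMap:
    """Load a height map from a text matrix + JSON sidecar.

    The sidecar ``<path>.json`` must define ``pixel_size`` (nm/px); a
    missing or garbled sidecar, ragged rows, or non-numeric/NaN cells all
    raise :class:`FormatError`.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta["pixel_size"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"garbled sidecar {sidecar}: {exc}") from exc

    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    if not rows:
        raise FormatError(f"{path}: empty matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows")
    heights = np.array(rows, dtype=float)
    if not np.isfinite(heights).all():
        raise FormatError(f"{path}: non-finite heights")
    return HeightMap(heights, pixel_size, name=str(meta.get("name", path.stem)))


def write_heightmap(hmap: HeightMap, path: str | Path) -> None:
    """Write a height map as text matrix + sidecar; round-trips losslessly."""
    path = Path(path)
    # %.17g preserves float64 exactly
    np.savetxt(path, hmap.heights, fmt="%.17g")
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size": hmap.pixel_size, "name": hmap.name,
                    "shape": list(hmap.shape), "units": "nm"}, indent=1)
    )


def read_xy(path: str | Path, units: tuple[str, str] = ("", "")) -> XYSeries:
    """Load a two-column numeric table as an :class:`XYSeries`.

    Accepts comma or whitespace delimiters and an optional single header
    line.  Rows are sorted by x and duplicate abscissae collapsed by mean.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         header=None, skip_blank_lines=True)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse table: {exc}") from exc
    # drop a header line if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise FormatError(f"{path}: non-numeric values")
    if len(df) < 3:
        raise InsufficientDataError(f"{path}: fewer than 3 data rows")
    grouped = df.groupby(df.columns[0], sort=True).mean()
    return XYSeries(grouped.index.to_numpy(float), grouped.iloc[:, 0].to_numpy(float),
                    units=units)


def write_xy(series: XYSeries, path: str | Path, header: tuple[str, str] | None = None) -> None:
    """Write an XYSeries as two-column CSV (optional header row)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header is not None:
            fh.write(f"{header[0]},{header[1]}\n")
        for xv, yv in zip(series.x, series.y):
            fh.write(f"{xv:.17g},{yv:.17g}\n")
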