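"""Gridded habitat-suitability and cost layers, with ESRI ASCII grid I/O.

Grids are stored row-major with row 0 at the TOP of the map (the .asc
convention); ``origin`` is the lower-left corner.  NODATA cells are carried
as NaN in memory and written back with the declared sentinel.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .datatypes import ConfigurationError, InputError

__all__ = [
    "Raster",
    "SuitabilityRaster",
    "CostRaster",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class Raster:
    """A single-band planar grid.

    Parameters
    ----------
    values : ndarray
        ``(n_rows, n_cols)`` float array; NaN marks NODATA.
    cell_size : float
        Edge length of a (square) cell in planar units.
    origin : tuple
        ``(xllcorner, yllcorner)`` of the grid.
    nodata : float
        Sentinel used when writing to disk.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InputError("raster values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Planar (x, y) of a cell center; row 0 is the top row."""
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell whose center is nearest to (x, y)."""
        col = int(np.clip(np.floor((x - self.origin[0]) / self.cell_size), 0, self.n_cols - 1))
        row_from_bottom = int(
            np.clip(np.floor((y - self.origin[1]) / self.cell_size), 0, self.n_rows - 1)
        )
        return self.n_rows - 1 - row_from_bottom, col

    def copy_with(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))


class SuitabilityRaster(Raster):
    """Habitat suitability in [0, 1] (e.g. SDM logistic output)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        defined = self.values[~np.isnan(self.values)]
        if defined.size and ((defined < 0) | (defined > 1)).any():
            raise InputError("suitability values must lie in [0, 1]")


class CostRaster(Raster):
    """Dispersal-cost (friction) layer; strictly positive where defined."""

    def __post_init__(self) -> None:
        super().__post_init__()
        defined = self.values[~np.isnan(self.values)]
        if defined.size and (defined <= 0).any():
            raise InputError("cost values must be strictly positive where defined")


def read_ascii_grid(path: str | Path, cls: type[Raster] = Raster) -> Raster:
    """Read an ESRI ASCII grid (.asc).

    The header accepts the standard six keys in any case; ``xllcenter`` /
    ``yllcenter`` are converted to corner coordinates.
    """
    text = Path(path).read_text()
    return _parse_ascii_grid(text, cls)


def _parse_ascii_grid(text: str, cls: type[Raster] = Raster) -> Raster:
    header: dict[str, float] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "xllcenter", "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise InputError(f"ASCII grid header is missing '{key}'")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2
    else:
        xll = 0.0
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cell / 2
    else:
        yll = 0.0
    nodata = header.get("nodata_value", -9999.0)
    body = "\n".join(lines[i:])
    values = np.loadtxt(io.StringIO(body)).reshape(n_rows, n_cols)
    values = np.where(values == nodata, np.nan, values)
    return cls(values=values, cell_size=cell, origin=(xll, yll), nodata=nodata)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid (.asc)."""
    path = Path(path)
    out = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6g}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6g}\n")
        fh.write(f"cellsize {raster.cell_size:.6g}\n")
        fh.write(f"NODATA_value {raster.nodata:.6g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")
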