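"""The ESRI ASCII raster container and its reader/writer.

Kept free of intra-package imports so every other module can depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DimensionError, FormatError, ValidationError

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class RasterGrid:
    """A georeferenced 2-D cell array; row 0 is the northernmost row."""

    values: np.ndarray
    x_ll: float = 0.0
    y_ll: float = 0.0
    cell_size: float = 5.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.cell_size <= 0:
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where a cell holds the nodata sentinel."""
        return self.values == self.nodata_value

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_sum(self) -> float:
        """Sum over data cells only; nodata never participates in arithmetic."""
        return float(self.values[self.valid_mask].sum())

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing with different values."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            x_ll=self.x_ll,
            y_ll=self.y_ll,
            cell_size=self.cell_size,
            nodata_value=self.nodata_value,
        )


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid.

    Raises
    ------
    FormatError
        If any of the six header lines is malformed (the message names the
        offending line).
    DimensionError
        If the data block does not match the declared ``nrows``/``ncols``.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: expected a six-line ESRI ASCII header")
    header: dict[str, float] = {}
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed header line {i + 1}: {line!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise FormatError(f"{path}: unknown header key on line {i + 1}: {parts[0]!r}")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value on line {i + 1}: {parts[1]!r}") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: header missing keys {missing}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    data = np.array(" ".join(lines[6:]).split(), dtype=float)
    if data.size != n_rows * n_cols:
        raise DimensionError(
            f"{path}: data block has {data.size} values, expected {n_rows}x{n_cols}"
        )
    return RasterGrid(
        values=data.reshape(n_rows, n_cols),
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=header["nodata_value"],
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write *grid* as ESRI ASCII; integer grids round-trip exactly."""
    path = Path(path)
    integral = np.all(grid.values == np.round(grid.values)) and np.all(
        np.abs(grid.values) < 1e15
    )
    fmt = "%d" if integral else "%.10g"
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_ll:.10g}\n")
        fh.write(f"yllcorner {grid.y_ll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        nodata = grid.nodata_value
        fh.write(f"nodata_value {int(nodata) if nodata == int(nodata) else nodata}\n")
        np.savetxt(fh, grid.values, fmt=fmt, delimiter=" ")
    return path


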