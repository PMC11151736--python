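"""Daily road-surface contaminant deposition.

The deposition chain converts a per-kilometre tire-wear emission rate into a
per-cell areal rate, applies the chemical mass fractions, scales each road
cell by its min-max normalised traffic count, and zeroes every cell that is
not chained upslope of a storm-drain inlet.  The same grid is applied every
simulation day; no weekday or seasonal traffic modulation is represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import DimensionError, DomainError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .grid_io import RasterGrid

logger = logging.getLogger(__name__)


@dataclass
class DepositionParams:
    """Deposition parameters.

    trwp
        Tire road wear particle emission, mg per km driven per day.
    cell_resolution
        Grid cell edge length in metres.
    tc_fraction
        Mass fraction of tire material that is the parent antiozonant.
    cc_fraction
        Fraction of the parent converted to the quinone (midpoint of the
        reported 1%-75% theoretical range).
    alpha
        Calibration scalar, left at 1.0.
    """

    trwp: float = 100.0
    cell_resolution: float = 5.0
    tc_fraction: float = 0.02
    cc_fraction: float = 0.38
    alpha: float = 1.0

    def validate(self) -> "DepositionParams":
        if self.trwp < 0:
            raise ValidationError(f"trwp must be >= 0, got {self.trwp}")
        if self.cell_resolution <= 0:
            raise ValidationError(f"cell_resolution must be > 0, got {self.cell_resolution}")
        for name in ("tc_fraction", "cc_fraction", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        return self


def trwp_adj(trwp: float) -> float:
    """mg km^-1 day^-1 -> g m^-1 day^-1 (factor 1e-6 by dimensional analysis)."""
    if trwp < 0:
        raise DomainError(f"trwp must be >= 0, got {trwp}")
    return trwp * 1e-6


def trwp_pixel(trwp_adj_value: float, cell_resolution: float) -> float:
    """g m^-1 day^-1 -> g m^-2 day^-1: one cell length of road spread over
    one cell area, i.e. division by the cell edge length."""
    if cell_resolution <= 0:
        raise DomainError(f"cell_resolution must be > 0, got {cell_resolution}")
    cell_area = cell_resolution * cell_resolution
    return trwp_adj_value * cell_resolution / cell_area


def trwp_6ppdq(trwp_pixel_value: float, params: DepositionParams) -> float:
    """Maximum per-cell quinone deposition: pixel rate times the tire-content
    and conversion fractions and the calibration scalar."""
    params.validate()
    return trwp_pixel_value * params.tc_fraction * params.cc_fraction * params.alpha


def max_cell_deposition(params: DepositionParams) -> float:
    """Deposition at the maximum-traffic cell for *params* (g m^-2 day^-1)."""
    return trwp_6ppdq(trwp_pixel(trwp_adj(params.trwp), params.cell_resolution), params)


def traffic_scalar(
    traffic_count: "RasterGrid", scaling_mask: np.ndarray | None = None
) -> "RasterGrid":
    """Min-max scale traffic counts to [0, 1] per road cell.

    Scaling uses the road cells inside *scaling_mask* (default: all cells
    with a traffic count).  The minimum count maps to 0 and the maximum to 1.
    If every count is equal (including a single road cell) all scalars are
    1.0 and a warning is logged.
    """
    valid = traffic_count.valid_mask
    subset = valid
    if scaling_mask is not None:
        if scaling_mask.shape != traffic_count.shape:
            raise DimensionError("scaling_mask shape does not match traffic grid")
        if (valid & scaling_mask).any():
            subset = valid & scaling_mask
    if not subset.any():
        raise DomainError("no road cells with traffic counts")
    counts = traffic_count.values[subset]
    lo, hi = counts.min(), counts.max()
    out = np.zeros(traffic_count.shape)
    if hi == lo:
        logger.warning("all traffic counts equal (%s); scalars set to 1.0", lo)
        out[valid] = 1.0
    else:
        # min/max come from the scaling subset; every counted cell is scaled
        # with them and clipped, so counts outside the subset's range saturate
        out[valid] = np.clip((traffic_count.values[valid] - lo) / (hi - lo), 0.0, 1.0)
    return traffic_count.copy_with(out)


def deposition_grid(
    params: DepositionParams,
    traffic: "RasterGrid",
    mask: np.ndarray,
    scaling_mask: np.ndarray | None = None,
) -> "RasterGrid":
    """Daily deposition grid (g m^-2 day^-1), nonzero only on *mask* cells.

    *mask* is the chained-upslope-of-inlet road mask; traffic scaling spans
    the road cells of *scaling_mask* when given (e.g. the delineated
    watershed), else all counted cells.
    """
    if mask.shape != traffic.shape:
        raise DimensionError(
            f"mask shape {mask.shape} does not match traffic grid {traffic.shape}"
        )
    ceiling = max_cell_deposition(params)
    scalars = traffic_scalar(traffic, scaling_mask)
    values = np.where(mask, ceiling * scalars.values, 0.0)
    return traffic.copy_with(values)
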