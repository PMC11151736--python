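"""Daily bucket-and-route hydrology.

A deliberately minimal scheme sufficient to carry the contaminant:

* impervious cells convert all rain to runoff; pervious cells infiltrate up
  to a daily capacity and the headroom of soil layer 1, excess runs off;
* surface water (and any dissolved mass riding on it) moves to the D8
  successor, is fully intercepted at storm-drain inlets and delivered the
  same day to the MS4 outfall cell or the WWTP sink, and may re-infiltrate
  while crossing pervious cells;
* the four-layer soil column percolates a fixed daily fraction of the water
  held above field capacity, the bottom layer drains laterally to the D8
  successor, and lateral water reaching a stream cell or a terminal becomes
  same-day baseflow at the pour point.

All storages are depths in mm over the cell; volumes are m^3
(mm * m^2 / 1000).  One mm over one m^2 is one litre, which keeps the
solute arithmetic simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import ConservationError, DomainError, ValidationError
from .watershed import (
    IMPERVIOUS_CODES,
    PERVIOUS,
    STREAM,
    TERMINAL,
    WWTP,
    FlowField,
    StormwaterNetwork,
    effective_downstream,
    effective_topo_order,
)

if TYPE_CHECKING:  # pragma: no cover
    from .grid_io import RasterGrid

_KNOWN_CODES = set(IMPERVIOUS_CODES) | {PERVIOUS, STREAM}


@dataclass
class HydrologyParams:
    """Constants of the bucket scheme; every one is a config key."""

    infiltration_capacity_mm: float = 20.0  # max daily infiltration, pervious cells
    percolation_fraction: float = 0.5  # daily fraction of above-field-capacity water
    lateral_fraction: float = 0.1  # daily fraction draining from the bottom layer
    et_mm_dry: float = 2.0  # daily layer-1 draw, June-September
    et_mm_wet: float = 0.5  # daily layer-1 draw, October-May
    porosity: float = 0.45
    field_capacity: float = 0.30
    layer_thickness_m: tuple[float, float, float, float] = (0.1, 0.2, 0.3, 0.4)
    bulk_density_kg_m3: float = 1300.0
    dry_season_months: tuple[int, ...] = (6, 7, 8, 9)

    def __post_init__(self) -> None:
        self.layer_thickness_m = tuple(float(t) for t in self.layer_thickness_m)
        self.dry_season_months = tuple(int(m) for m in self.dry_season_months)

    def validate(self) -> "HydrologyParams":
        for name in ("infiltration_capacity_mm", "et_mm_dry", "et_mm_wet", "bulk_density_kg_m3"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("percolation_fraction", "lateral_fraction", "porosity", "field_capacity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.field_capacity > self.porosity:
            raise ValidationError(
                f"field_capacity ({self.field_capacity}) must be <= porosity ({self.porosity})"
            )
        if len(self.layer_thickness_m) != 4 or any(t <= 0 for t in self.layer_thickness_m):
            raise ValidationError("layer_thickness_m must be 4 positive values")
        return self

    @property
    def capacity_mm(self) -> np.ndarray:
        """Per-layer saturated storage, mm."""
        return self.porosity * np.asarray(self.layer_thickness_m) * 1000.0

    @property
    def field_capacity_mm(self) -> np.ndarray:
        return self.field_capacity * np.asarray(self.layer_thickness_m) * 1000.0

    def et_rate(self, month: int) -> float:
        return self.et_mm_dry if month in self.dry_season_months else self.et_mm_wet


@dataclass
class SoilColumnState:
    """Per-cell soil water in 4 layers (mm)."""

    water_mm: np.ndarray  # (4, n_rows, n_cols)
    capacity_mm: np.ndarray  # (4,)
    field_capacity_mm: np.ndarray  # (4,)

    @classmethod
    def initial(cls, shape: tuple[int, int], params: HydrologyParams, fill_fraction: float = 0.5):
        """Start each layer at *fill_fraction* of field capacity."""
        cap = params.capacity_mm
        fc = params.field_capacity_mm
        water = np.broadcast_to((fc * fill_fraction)[:, None, None], (4, *shape)).copy()
        return cls(water_mm=water, capacity_mm=cap, field_capacity_mm=fc)

    @property
    def total_mm(self) -> np.ndarray:
        return self.water_mm.sum(axis=0)

    def check_bounds(self) -> None:
        if np.any(self.water_mm < -1e-9):
            raise ConservationError("negative soil water storage")
        over = self.water_mm - self.capacity_mm[:, None, None]
        if np.any(over > 1e-6):
            raise ConservationError("soil water storage above saturation")


def generate_runoff(
    precip_mm: float,
    land_cover: "RasterGrid",
    soil: SoilColumnState,
    params: HydrologyParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Split rainfall into (runoff_mm, infiltration_mm) grids.

    Impervious and stream cells shed all rain; pervious cells infiltrate up
    to the daily capacity and layer-1 headroom, the excess runs off.
    """
    if precip_mm < 0:
        raise DomainError(f"precip must be >= 0, got {precip_mm}")
    cover = land_cover.values.astype(int)
    known = np.isin(cover, sorted(_KNOWN_CODES)) | ~land_cover.valid_mask
    if not known.all():
        bad = int(cover[~known].ravel()[0])
        raise DomainError(f"unknown land-cover code {bad}")
    pervious = (cover == PERVIOUS) & land_cover.valid_mask
    headroom = soil.capacity_mm[0] - soil.water_mm[0]
    infil = np.where(
        pervious,
        np.minimum(np.minimum(precip_mm, params.infiltration_capacity_mm), np.maximum(headroom, 0.0)),
        0.0,
    )
    runoff = np.where(land_cover.valid_mask, precip_mm - infil, 0.0)
    return runoff, infil


@dataclass
class DailyWaterFluxes:
    """Outcome of one day's surface routing (water plus any dissolved mass)."""

    pour_point_discharge_m3: float
    wwtp_export_m3: float
    boundary_export_m3: float
    runon_infiltration_mm: np.ndarray  # (nr, nc) extra infiltration while routing
    inlet_interception_m3: np.ndarray  # flat, volume intercepted per inlet cell
    surface_inflow_m3: np.ndarray  # flat, routed inflow arriving at each cell
    mass_to_stream_g: float = 0.0
    mass_to_wwtp_g: float = 0.0
    mass_to_boundary_g: float = 0.0
    mass_infiltrated_g: np.ndarray | None = None  # (nr, nc), joins soil layer 1


def route_surface(
    runoff_mm: np.ndarray,
    flow: FlowField,
    network: StormwaterNetwork | None = None,
    land_cover: "RasterGrid | None" = None,
    pour_index: int | None = None,
    dissolved_g: np.ndarray | None = None,
    runon_capacity_mm: np.ndarray | None = None,
    topo_order: np.ndarray | None = None,
) -> DailyWaterFluxes:
    """Route surface water (and dissolved mass) downslope in one daily pass.

    Every cell's outflow (local runoff + inflow) moves to its effective
    successor; inlets intercept everything and deliver to the outfall or the
    WWTP the same day.  When *runon_capacity_mm* is given, water crossing a
    pervious cell infiltrates up to that capacity and carries a proportional
    share of dissolved mass into the soil.
    """
    nr, nc = flow.shape
    area = flow.cell_size**2
    eff = effective_downstream(flow, network)
    if topo_order is None:
        topo_order = effective_topo_order(flow, network)
    gen_m3 = np.asarray(runoff_mm, dtype=float).ravel() * area / 1000.0
    if np.any(gen_m3 < 0):
        raise DomainError("negative runoff")
    mass = None if dissolved_g is None else np.asarray(dissolved_g, dtype=float).ravel()
    cover = None if land_cover is None else land_cover.values.astype(int).ravel()
    cap_m3 = None
    if runon_capacity_mm is not None:
        if cover is None:
            raise ValidationError("runon infiltration requires land_cover")
        cap_m3 = np.maximum(np.asarray(runon_capacity_mm, dtype=float).ravel(), 0.0) * area / 1000.0

    inflow = np.zeros(nr * nc)
    inflow_mass = np.zeros(nr * nc)
    runon = np.zeros(nr * nc)
    interception = np.zeros(nr * nc)
    inlet_cells = set()
    if network is not None:
        for link in network.links:
            inlet_cells.add(link.inlet[0] * nc + link.inlet[1])

    pour = wwtp = boundary = 0.0
    m_stream = m_wwtp = m_boundary = 0.0
    m_infil = np.zeros(nr * nc)

    for i in topo_order:
        w = inflow[i] + gen_m3[i]
        m = (inflow_mass[i] + mass[i]) if mass is not None else 0.0
        if w <= 0.0:
            if m > 0.0:
                raise ConservationError(f"dissolved mass with no carrier water at cell {i}")
            continue
        if cap_m3 is not None and cover[i] == PERVIOUS and cap_m3[i] > 0.0:
            take = min(w, cap_m3[i])
            frac = take / w
            runon[i] += take
            if mass is not None:
                m_infil[i] += m * frac
                m -= m * frac
            w -= take
            if w <= 0.0:
                continue
        if i in inlet_cells:
            interception[i] = w
        succ = int(eff[i])
        if succ == WWTP:
            wwtp += w
            m_wwtp += m
        elif succ == TERMINAL:
            if pour_index is not None and i == pour_index:
                pour += w
                m_stream += m
            elif pour_index is None:
                pour += w
                m_stream += m
            else:
                boundary += w
                m_boundary += m
        else:
            inflow[succ] += w
            if mass is not None:
                inflow_mass[succ] += m

    return DailyWaterFluxes(
        pour_point_discharge_m3=pour,
        wwtp_export_m3=wwtp,
        boundary_export_m3=boundary,
        runon_infiltration_mm=(runon / area * 1000.0).reshape(nr, nc),
        inlet_interception_m3=interception,
        surface_inflow_m3=inflow,
        mass_to_stream_g=m_stream,
        mass_to_wwtp_g=m_wwtp,
        mass_to_boundary_g=m_boundary,
        mass_infiltrated_g=m_infil.reshape(nr, nc) if mass is not None else None,
    )


def evapotranspiration_step(
    soil: SoilColumnState,
    land_cover: "RasterGrid",
    rate_mm: float,
) -> float:
    """Draw water (not solute) from layer 1 of pervious cells; returns the
    total volume removed (m^3 over the grid)."""
    pervious = land_cover.values.astype(int) == PERVIOUS
    draw = np.where(pervious, np.minimum(rate_mm, soil.water_mm[0]), 0.0)
    soil.water_mm[0] -= draw
    area = land_cover.cell_size**2
    return float(draw.sum()) * area / 1000.0


@dataclass
class SubsurfaceFluxes:
    """Record of one day's soil-water movements, with the pre-move storages
    needed to advect dissolved mass by proportion."""

    pre_perc_storage_mm: np.ndarray  # (3, nr, nc) storage when percolation left
    percolation_mm: np.ndarray  # (3, nr, nc) layer l -> l+1
    pre_lateral_storage_mm: np.ndarray  # (nr, nc) bottom layer before lateral
    lateral_out_mm: np.ndarray  # (nr, nc)
    lateral_stored_mm: np.ndarray  # (nr, nc) part of out stored at successor
    lateral_baseflow_mm: np.ndarray  # (nr, nc) part of out leaving as baseflow
    lateral_dest: np.ndarray  # flat successor index, TERMINAL if none
    baseflow_m3: float = 0.0
    saturation_return_m3: float = 0.0  # lateral inflow rejected by a full cell

    @property
    def has_flow(self) -> bool:
        return bool(self.percolation_mm.any() or self.lateral_out_mm.any())


def subsurface_step(
    soil: SoilColumnState,
    flow: FlowField,
    params: HydrologyParams,
    land_cover: "RasterGrid",
    pour_index: int,
) -> SubsurfaceFluxes:
    """Percolate each layer's above-field-capacity water downward (capped by
    the receiving layer's headroom) and drain the bottom layer laterally to
    the D8 successor; lateral water reaching a stream cell, a terminal, or a
    saturated receiver leaves as baseflow at the pour point.  Mutates *soil*
    in place and returns the flux record."""
    nr, nc = flow.shape
    area = flow.cell_size**2
    w = soil.water_mm
    cap = soil.capacity_mm
    fc = soil.field_capacity_mm

    pre_perc = np.zeros((3, nr, nc))
    perc = np.zeros((3, nr, nc))
    for l in range(3):
        pre_perc[l] = w[l]
        excess = np.maximum(w[l] - fc[l], 0.0)
        headroom = np.maximum(cap[l + 1] - w[l + 1], 0.0)
        move = np.minimum(params.percolation_fraction * excess, headroom)
        w[l] -= move
        w[l + 1] += move
        perc[l] = move

    pre_lat = w[3].copy()
    lat_out = params.lateral_fraction * np.maximum(w[3] - fc[3], 0.0)
    w[3] -= lat_out

    cover = land_cover.values.astype(int).ravel()
    lat_flat = lat_out.ravel()
    w4 = w[3].ravel()
    stored = np.zeros(nr * nc)
    base = np.zeros(nr * nc)
    sat_return = 0.0
    baseflow = 0.0
    src_cells = np.flatnonzero(lat_flat > 0.0)
    # honour topological order among the draining cells so cascaded inflows
    # see up-to-date storages
    pos = np.empty(nr * nc, dtype=np.int64)
    pos[flow.topo_order] = np.arange(nr * nc)
    for i in src_cells[np.argsort(pos[src_cells])]:
        out = lat_flat[i]
        succ = int(flow.downstream[i])
        if succ < 0 or cover[succ] == STREAM or succ == pour_index:
            base[i] = out
            baseflow += out
            continue
        headroom = cap[3] - w4[succ]
        s = min(out, max(headroom, 0.0))
        w4[succ] += s
        stored[i] = s
        if out > s:
            base[i] = out - s
            baseflow += out - s
            sat_return += out - s
    w[3] = w4.reshape(nr, nc)

    return SubsurfaceFluxes(
        pre_perc_storage_mm=pre_perc,
        percolation_mm=perc,
        pre_lateral_storage_mm=pre_lat,
        lateral_out_mm=lat_out,
        lateral_stored_mm=stored.reshape(nr, nc),
        lateral_baseflow_mm=base.reshape(nr, nc),
        lateral_dest=flow.downstream.copy(),
        baseflow_m3=baseflow * area / 1000.0,
        saturation_return_m3=sat_return * area / 1000.0,
    )
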