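"""End-to-end simulation orchestration.

The fixed daily operator-splitting order is:

1. deposit the daily contaminant grid on chained road cells;
2. split rainfall into runoff and infiltration;
3. wash surface mass into locally generated runoff (solubility-capped);
4. route surface water and dissolved mass downslope and through pipes,
   with re-infiltration on pervious cells;
5. evapotranspiration draw from soil layer 1 (water only);
6. re-equilibrate sorbed/aqueous phases in every soil layer;
7. percolate/drain soil water and advect aqueous mass with it;
8. first-order decay of soil pools;
9. update and check the mass-balance ledger (abort on failure).

Changing the output cadence never changes the state trajectory; identical
inputs and seed give bit-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deposition import deposition_grid
from .errors import ConservationError
from .fate import (
    ContaminantState,
    MassBalanceLedger,
    decay_step,
    deposit,
    mass_balance_check,
    partition_soil_column,
    vertical_lateral_transport,
    washoff,
)
from .grid_io import RasterGrid, SimulationConfig, WeatherSeries, write_ascii_grid
from .hydrology import (
    SoilColumnState,
    evapotranspiration_step,
    generate_runoff,
    route_surface,
    subsurface_step,
)
from .reporting import PourPointSeries, concentration_series, mass_balance_summary
from .watershed import ROAD, Watershed, delineate, effective_topo_order, upslope_of_inlet_mask

logger = logging.getLogger(__name__)

MASS_BALANCE_TOLERANCE = 1e-9


@dataclass
class WaterLedger:
    """Cumulative water volumes (m^3) for the whole run."""

    precip_m3: float = 0.0
    discharge_m3: float = 0.0
    wwtp_m3: float = 0.0
    boundary_m3: float = 0.0
    et_m3: float = 0.0
    initial_soil_m3: float = 0.0

    def residual(self, soil_m3: float) -> float:
        delta = soil_m3 - self.initial_soil_m3
        imbalance = self.precip_m3 - self.discharge_m3 - self.wwtp_m3 - self.boundary_m3 - self.et_m3 - delta
        return abs(imbalance) / max(self.precip_m3, 1e-30)


@dataclass
class SimulationResult:
    series: PourPointSeries
    daily: pd.DataFrame  # extended per-day table
    ledger: MassBalanceLedger
    water: WaterLedger
    state: ContaminantState
    soil: SoilColumnState
    deposition: RasterGrid
    hotspot_surface_mean: np.ndarray
    hotspot_soil_mean: np.ndarray
    hotspot_surface_max: np.ndarray
    hotspot_soil_max: np.ndarray
    manifest: dict
    surface_history: list = field(default_factory=list)  # (date, grid) if recorded
    soil_history: list = field(default_factory=list)


def _config_hash(config: SimulationConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_simulation(
    watershed: Watershed,
    weather: WeatherSeries,
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    record_daily_grids: bool = False,
) -> SimulationResult:
    """Run the daily loop over the whole weather series."""
    config = (config or SimulationConfig()).validate()
    dep_p = config.deposition
    con_p = config.contaminant
    hyd_p = config.hydrology

    nr, nc = watershed.shape
    area = watershed.cell_area
    cover = watershed.land_cover
    cover_int = cover.values.astype(int)
    pour_idx = watershed.pour_index
    flow = watershed.flow
    network = watershed.network
    eff_order = effective_topo_order(flow, network)

    contributing = delineate(flow, watershed.pour_point, network)
    inlet_mask = upslope_of_inlet_mask(flow, cover, network)
    scaling_mask = contributing & (cover_int == ROAD)
    if not scaling_mask.any():
        scaling_mask = cover_int == ROAD
    daily_dep = deposition_grid(dep_p, watershed.traffic_count, inlet_mask, scaling_mask)

    state = ContaminantState.zero((nr, nc))
    soil = SoilColumnState.initial((nr, nc), hyd_p)
    ledger = MassBalanceLedger()
    water = WaterLedger(initial_soil_m3=float(soil.water_mm.sum()) * area / 1000.0)
    valid_cells = int(cover.valid_mask.sum())

    manifest = {
        "config_hash": _config_hash(config),
        "software_version": __version__,
        "random_seed": config.random_seed,
        "start_date": f"{weather.dates[0]:%Y-%m-%d}",
        "end_date": f"{weather.dates[-1]:%Y-%m-%d}",
        "n_days": len(weather),
        "grid_shape": [nr, nc],
        "cell_size_m": watershed.cell_size,
        "operator_order": [
            "deposit",
            "generate_runoff",
            "washoff",
            "route_surface",
            "evapotranspiration",
            "partition",
            "subsurface_transport",
            "decay",
            "mass_balance_check",
        ],
        "status": "running",
        "outputs": [],
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    n_days = len(weather)
    discharge = np.zeros(n_days)
    loads = np.zeros(n_days)
    precip_series = np.zeros(n_days)
    surf_store = np.zeros(n_days)
    soil_store = np.zeros(n_days)
    wwtp_series = np.zeros(n_days)

    hs_surf_sum = np.zeros((nr, nc))
    hs_soil_sum = np.zeros((nr, nc))
    hs_surf_max = np.zeros((nr, nc))
    hs_soil_max = np.zeros((nr, nc))
    surface_history: list = []
    soil_history: list = []

    for day in range(n_days):
        date = weather.dates[day]
        precip = float(weather.precip_mm[day])
        tavg = float(weather.tavg_c[day])

        deposit(state, daily_dep, ledger)

        runoff_mm, infil_mm = generate_runoff(precip, cover, soil, hyd_p)
        soil.water_mm[0] += infil_mm
        water.precip_m3 += precip * valid_cells * area / 1000.0

        dissolved = washoff(state, runoff_mm, cover, con_p)

        runon_cap = np.maximum(
            np.minimum(
                hyd_p.infiltration_capacity_mm - infil_mm,
                soil.capacity_mm[0] - soil.water_mm[0],
            ),
            0.0,
        )
        stream_before = ledger.stream_export_g
        fluxes = route_surface(
            runoff_mm,
            flow,
            network,
            cover,
            pour_idx,
            dissolved_g=dissolved.ravel(),
            runon_capacity_mm=runon_cap,
            topo_order=eff_order,
        )
        soil.water_mm[0] += fluxes.runon_infiltration_mm
        state.aqueous_g_m2[0] += fluxes.mass_infiltrated_g / area
        ledger.stream_export_g += fluxes.mass_to_stream_g
        ledger.wwtp_export_g += fluxes.mass_to_wwtp_g
        ledger.boundary_export_g += fluxes.mass_to_boundary_g
        water.discharge_m3 += fluxes.pour_point_discharge_m3
        water.wwtp_m3 += fluxes.wwtp_export_m3
        water.boundary_m3 += fluxes.boundary_export_m3

        water.et_m3 += evapotranspiration_step(soil, cover, hyd_p.et_rate(date.month))

        partition_soil_column(state, soil, watershed.foc_by_layer, hyd_p, con_p, area)

        sub = subsurface_step(soil, flow, hyd_p, cover, pour_idx)
        vertical_lateral_transport(state, sub, ledger, area)
        water.discharge_m3 += sub.baseflow_m3

        decay_step(
            state, tavg, soil, con_p, ledger, area, q10=con_p.q10, t_opt_c=con_p.t_opt_c
        )

        try:
            mass_balance_check(ledger, state, area, MASS_BALANCE_TOLERANCE)
        except ConservationError as exc:
            raise ConservationError(f"{date:%Y-%m-%d}: {exc}") from exc
        soil.check_bounds()
        state.check_nonnegative()

        discharge[day] = fluxes.pour_point_discharge_m3 + sub.baseflow_m3
        loads[day] = ledger.stream_export_g - stream_before
        precip_series[day] = precip
        surf_store[day] = state.surface_storage_g(area)
        soil_store[day] = state.soil_storage_g(area)
        wwtp_series[day] = fluxes.wwtp_export_m3

        soil_total = state.aqueous_g_m2.sum(axis=0) + state.sorbed_g_m2.sum(axis=0)
        hs_surf_sum += state.surface_g_m2
        hs_soil_sum += soil_total
        np.maximum(hs_surf_max, state.surface_g_m2, out=hs_surf_max)
        np.maximum(hs_soil_max, soil_total, out=hs_soil_max)
        if record_daily_grids:
            surface_history.append((date, state.surface_g_m2.copy()))
            soil_history.append((date, soil_total))

    series = concentration_series(weather.dates, loads, discharge)
    daily = series.frame.copy()
    daily["precip_mm"] = precip_series
    daily["surface_storage_g"] = surf_store
    daily["soil_storage_g"] = soil_store
    daily["wwtp_m3"] = wwtp_series

    manifest["status"] = "complete"
    manifest["mass_balance_residual"] = ledger.residual(state, area)
    manifest["water_balance_residual"] = water.residual(
        float(soil.water_mm.sum()) * area / 1000.0
    )

    result = SimulationResult(
        series=series,
        daily=daily,
        ledger=ledger,
        water=water,
        state=state,
        soil=soil,
        deposition=daily_dep,
        hotspot_surface_mean=hs_surf_sum / n_days,
        hotspot_soil_mean=hs_soil_sum / n_days,
        hotspot_surface_max=hs_surf_max,
        hotspot_soil_max=hs_soil_max,
        manifest=manifest,
        surface_history=surface_history,
        soil_history=soil_history,
    )
    if out_path is not None:
        _write_outputs(result, watershed, out_path)
    return result


def _write_outputs(result: SimulationResult, watershed: Watershed, out_path: Path) -> None:
    template = watershed.dem
    outputs = []

    def register(p: Path) -> None:
        outputs.append(p.name)

    series_path = out_path / "pour_point.csv"
    result.series.to_csv(series_path)
    register(series_path)

    daily_path = out_path / "daily.csv"
    d = result.daily.copy()
    d["date"] = pd.DatetimeIndex(d["date"]).strftime("%Y-%m-%d")
    d.to_csv(daily_path, index=False)
    register(daily_path)

    for name, grid in (
        ("deposition.asc", result.deposition.values),
        ("hotspot_surface_mean.asc", result.hotspot_surface_mean),
        ("hotspot_soil_mean.asc", result.hotspot_soil_mean),
        ("hotspot_surface_max.asc", result.hotspot_surface_max),
        ("hotspot_soil_max.asc", result.hotspot_soil_max),
    ):
        p = out_path / name
        write_ascii_grid(template.copy_with(grid), p)
        register(p)

    balance_path = out_path / "mass_balance.txt"
    balance_path.write_text(
        mass_balance_summary(result.ledger, result.state.total_storage_g(watershed.cell_area))
        + "\n"
    )
    register(balance_path)

    result.manifest["outputs"] = outputs
    (out_path / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
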