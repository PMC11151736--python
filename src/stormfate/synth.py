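"""Self-contained synthetic watersheds and weather.

The generated domain is a V-shaped valley on a 5-m grid draining to a single
southern pour point, with a stream along the valley axis, north-south roads
carrying heterogeneous traffic, storm-drain inlets piped to riparian cells
near the stream (or to the WWTP for CSS links), and a wet/dry seasonal
rainfall regime (wet October-May, dry June-September).  Everything is
deterministic under the generator seed.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid_io import (
    RasterGrid,
    WeatherSeries,
    SimulationConfig,
    write_ascii_grid,
    write_config,
    write_weather_csv,
)
from .watershed import (
    OTHER_IMPERVIOUS,
    PERVIOUS,
    ROAD,
    ROOF,
    STREAM,
    PipeLink,
    StormwaterNetwork,
    Watershed,
    write_network_csv,
)

NODATA = -9999.0


@dataclass
class SynthSpec:
    """Parameters of the synthetic watershed and weather generator."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 5.0
    slope: float = 0.02  # down-valley gradient, m/m
    cross_slope_ratio: float = 0.25  # hillslope gradient as a fraction of slope
    road_spacing: int = 7  # columns between north-south roads
    inlet_spacing: int = 10  # road cells between storm-drain inlets
    traffic_range: tuple[int, int] = (100, 5000)  # vehicles/day
    foc_by_layer: tuple[float, float, float, float] = (0.03, 0.01, 0.005, 0.002)
    roof_fraction: float = 0.3  # chance a road-adjacent cell is a roof
    css_fraction: float = 0.2  # fraction of inlets on the combined system
    wet_storm_prob: float = 0.45
    wet_storm_mm: float = 8.0
    dry_storm_prob: float = 0.02
    dry_storm_mm: float = 2.0
    temp_mean_c: float = 11.0
    temp_amp_c: float = 7.0
    dry_months: tuple[int, ...] = (6, 7, 8, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        self.traffic_range = tuple(int(v) for v in self.traffic_range)
        self.foc_by_layer = tuple(float(f) for f in self.foc_by_layer)
        self.dry_months = tuple(int(m) for m in self.dry_months)

    def validate(self) -> "SynthSpec":
        if self.n_rows < 5 or self.n_cols < 5:
            raise ValidationError("grid must be at least 5x5")
        if self.slope <= 0:
            raise ValidationError(f"slope must be > 0, got {self.slope}")
        # keeps road columns draining due south so road chains stay intact
        if not 0 < self.cross_slope_ratio < np.sqrt(2.0) - 1.0:
            raise ValidationError(
                f"cross_slope_ratio must be in (0, sqrt(2)-1), got {self.cross_slope_ratio}"
            )
        if self.road_spacing < 1 or self.inlet_spacing < 1:
            raise ValidationError("spacings must be >= 1")
        lo, hi = self.traffic_range
        if lo < 0 or hi < lo:
            raise ValidationError(f"bad traffic_range {self.traffic_range}")
        for name in ("wet_storm_prob", "dry_storm_prob", "roof_fraction", "css_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        return self

    @property
    def axis_col(self) -> int:
        return self.n_cols // 2

    @property
    def pour_point(self) -> tuple[int, int]:
        return (self.n_rows - 1, self.axis_col)

    def road_columns(self) -> list[int]:
        """North-south road columns, avoiding the stream corridor."""
        protected = {self.axis_col - 1, self.axis_col, self.axis_col + 1}
        return [
            c
            for c in range(2, self.n_cols - 2, self.road_spacing)
            if c not in protected
        ]


def make_dem(spec: SynthSpec) -> RasterGrid:
    """V-shaped valley, pit-free by construction, draining to one southern
    pour point on the valley axis."""
    spec.validate()
    cs = spec.cell_size
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    cross = spec.cross_slope_ratio * spec.slope
    z = spec.slope * (spec.n_rows - 1 - rows) * cs + cross * np.abs(cols - spec.axis_col) * cs
    return RasterGrid(values=z.astype(float), cell_size=cs, nodata_value=NODATA)


def make_landcover_and_traffic(spec: SynthSpec, dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Grid-pattern roads with per-street traffic counts, one max-traffic
    arterial, roofs beside roads, a parking lot, and the axis stream."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.n_rows, spec.n_cols
    cover = np.full((nr, nc), PERVIOUS, dtype=float)
    traffic = np.full((nr, nc), NODATA)

    cover[:, spec.axis_col] = STREAM

    road_cols = spec.road_columns()
    lo, hi = spec.traffic_range
    for k, c in enumerate(road_cols):
        # roads stop one row short of the bottom boundary row
        cover[: nr - 1, c] = ROAD
        count = hi if k == 0 else int(rng.integers(lo, hi)) if hi > lo else hi
        traffic[: nr - 1, c] = count

    for c in road_cols:
        if c + 1 >= nc or c + 1 == spec.axis_col:
            continue
        roofs = (rng.random(nr - 1) < spec.roof_fraction) & (cover[: nr - 1, c + 1] == PERVIOUS)
        cover[: nr - 1, c + 1][roofs] = ROOF

    # one parking lot block: impervious but never a deposition surface
    if road_cols:
        c0 = road_cols[0] + 2
        if c0 + 2 < nc:
            block = cover[2:5, c0 : c0 + 3]
            block[block == PERVIOUS] = OTHER_IMPERVIOUS

    lc = RasterGrid(values=cover, cell_size=spec.cell_size, nodata_value=NODATA)
    tr = RasterGrid(values=traffic, cell_size=spec.cell_size, nodata_value=NODATA)
    return lc, tr


def make_network(spec: SynthSpec, land_cover: RasterGrid) -> StormwaterNetwork:
    """Inlets every ``inlet_spacing`` road cells, each piped to a riparian
    cell beside the stream (MS4) or removed to the WWTP (CSS).  Road cells
    below the lowest inlet of a street intentionally stay unchained."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    links: list[PipeLink] = []
    cover = land_cover.values.astype(int)
    axis = spec.axis_col
    for c in spec.road_columns():
        road_rows = np.flatnonzero(cover[:, c] == ROAD)
        if len(road_rows) == 0:
            continue
        # leave a tail of road cells downslope of the last inlet
        inlet_rows = road_rows[spec.inlet_spacing - 1 :: spec.inlet_spacing]
        if len(inlet_rows) and inlet_rows[-1] == road_rows[-1]:
            inlet_rows = inlet_rows[:-1]
        for r in inlet_rows:
            if rng.random() < spec.css_fraction:
                links.append(PipeLink(inlet=(int(r), c), dest=None, system_type="CSS"))
            else:
                dest_col = axis + 1 if c > axis else axis - 1
                links.append(
                    PipeLink(inlet=(int(r), c), dest=(int(r), dest_col), system_type="MS4")
                )
    return StormwaterNetwork(links=links)


def make_weather(spec: SynthSpec, year: int = 2020) -> WeatherSeries:
    """Daily precipitation and temperature for one calendar year: frequent
    wet-season storms October-May, sparse dry-season rain June-September,
    and a temperature sinusoid peaking in early August."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    n_days = 366 if calendar.isleap(year) else 365
    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    precip = np.zeros(n_days)
    for i, d in enumerate(dates):
        dry = d.month in spec.dry_months
        prob = spec.dry_storm_prob if dry else spec.wet_storm_prob
        mean = spec.dry_storm_mm if dry else spec.wet_storm_mm
        if rng.random() < prob and mean > 0:
            precip[i] = rng.exponential(mean)
    doy = np.arange(n_days)
    tavg = spec.temp_mean_c + spec.temp_amp_c * np.cos(2 * np.pi * (doy - 213) / n_days)
    return WeatherSeries(dates=dates, precip_mm=precip, tavg_c=tavg)


def build_watershed(spec: SynthSpec) -> Watershed:
    """Assemble the full synthetic domain with its derived flow field."""
    dem = make_dem(spec)
    land_cover, traffic = make_landcover_and_traffic(spec, dem)
    network = make_network(spec, land_cover)
    return Watershed.from_grids(
        dem=dem,
        land_cover=land_cover,
        traffic_count=traffic,
        network=network,
        pour_point=spec.pour_point,
        foc_by_layer=spec.foc_by_layer,
    )


def write_bundle(
    spec: SynthSpec,
    out_dir: str | Path,
    year: int = 2020,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the complete input bundle (grids, weather, network, config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem = make_dem(spec)
    land_cover, traffic = make_landcover_and_traffic(spec, dem)
    network = make_network(spec, land_cover)
    weather = make_weather(spec, year)
    cfg = config or SimulationConfig()
    cfg.random_seed = spec.seed
    paths = {
        "dem": write_ascii_grid(dem, out / "dem.asc"),
        "land_cover": write_ascii_grid(land_cover, out / "land_cover.asc"),
        "traffic": write_ascii_grid(traffic, out / "traffic.asc"),
        "weather": write_weather_csv(weather, out / "weather.csv"),
        "network": write_network_csv(network, out / "network.csv"),
        "config": write_config(cfg, out / "config.yaml"),
    }
    (out / "pour_point.txt").write_text(f"{spec.pour_point[0]} {spec.pour_point[1]}\n")
    paths["pour_point"] = out / "pour_point.txt"
    return paths
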