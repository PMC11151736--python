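"""Spatial and tabular I/O plus configuration loading.

Rasters use the six-line ESRI ASCII grid dialect (``ncols``, ``nrows``,
``xllcorner``, ``yllcorner``, ``cellsize``, ``nodata_value``; keys matched
case-insensitively, written lowercase).  Cell ``(0, 0)`` is the northwest
corner; ``xllcorner``/``yllcorner`` locate the southwest corner of the grid
per the format standard.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .deposition import DepositionParams
from .errors import (
    ContinuityError,
    DimensionError,
    FormatError,
    ValidationError,
)
from .fate import ContaminantParams
from .hydrology import HydrologyParams
from .raster import RasterGrid, read_ascii_grid, write_ascii_grid  # noqa: F401

@dataclass
class WeatherSeries:
    """Consecutive daily weather drivers: precipitation (mm/day) and mean
    air temperature (degrees C)."""

    dates: pd.DatetimeIndex
    precip_mm: np.ndarray
    tavg_c: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.precip_mm = np.asarray(self.precip_mm, dtype=float)
        self.tavg_c = np.asarray(self.tavg_c, dtype=float)
        n = len(self.dates)
        if len(self.precip_mm) != n or len(self.tavg_c) != n:
            raise DimensionError("weather columns must share one length")
        if n == 0:
            raise ValidationError("weather series is empty")
        dup = self.dates[self.dates.duplicated()]
        if len(dup):
            raise ContinuityError(f"duplicate dates: {list(dup.strftime('%Y-%m-%d'))}")
        expected = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        if not self.dates.equals(expected):
            missing = expected.difference(self.dates)
            raise ContinuityError(
                f"gap in dates; missing: {list(missing.strftime('%Y-%m-%d'))}"
            )
        if np.any(self.precip_mm < 0):
            bad = self.dates[self.precip_mm < 0][0]
            raise ValidationError(f"negative precipitation on {bad:%Y-%m-%d}")

    def __len__(self) -> int:
        return len(self.dates)


def read_weather_csv(path: str | Path) -> WeatherSeries:
    """Read a daily weather table with columns date, precip_mm, tavg_c."""
    df = pd.read_csv(path)
    required = {"date", "precip_mm", "tavg_c"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: weather CSV needs columns {sorted(required)}")
    dates = pd.to_datetime(df["date"])
    return WeatherSeries(
        dates=pd.DatetimeIndex(dates),
        precip_mm=df["precip_mm"].to_numpy(dtype=float),
        tavg_c=df["tavg_c"].to_numpy(dtype=float),
    )


def write_weather_csv(weather: WeatherSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "date": weather.dates.strftime("%Y-%m-%d"),
            "precip_mm": weather.precip_mm,
            "tavg_c": weather.tavg_c,
        }
    ).to_csv(path, index=False)
    return path


@dataclass
class SimulationConfig:
    """Full parameter set for one simulation run.

    Every field has a documented default; a config file only needs to list
    the keys it overrides.
    """

    deposition: DepositionParams = field(default_factory=DepositionParams)
    contaminant: ContaminantParams = field(default_factory=ContaminantParams)
    hydrology: HydrologyParams = field(default_factory=HydrologyParams)
    lc50_threshold: float = 95.0
    random_seed: int = 0
    output_dir: str | None = None
    grid_output_cadence: int = 0  # days between grid dumps; 0 disables

    def validate(self) -> "SimulationConfig":
        self.deposition.validate()
        self.contaminant.validate()
        self.hydrology.validate()
        if self.lc50_threshold <= 0:
            raise ValidationError(
                f"lc50_threshold must be > 0, got {self.lc50_threshold}"
            )
        if self.grid_output_cadence < 0:
            raise ValidationError("grid_output_cadence must be >= 0")
        return self

    def to_dict(self) -> dict:
        return {
            "deposition": dataclasses.asdict(self.deposition),
            "contaminant": dataclasses.asdict(self.contaminant),
            "hydrology": dataclasses.asdict(self.hydrology),
            "lc50_threshold": self.lc50_threshold,
            "random_seed": self.random_seed,
            "output_dir": self.output_dir,
            "grid_output_cadence": self.grid_output_cadence,
        }


def _apply_section(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValidationError(f"unknown {name} config keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Load a YAML config; absent keys are filled with the documented
    defaults and every default is overridable."""
    raw: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    known = {
        "deposition",
        "contaminant",
        "hydrology",
        "lc50_threshold",
        "random_seed",
        "output_dir",
        "grid_output_cadence",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = SimulationConfig(
        deposition=_apply_section(DepositionParams, raw.get("deposition", {}), "deposition"),
        contaminant=_apply_section(ContaminantParams, raw.get("contaminant", {}), "contaminant"),
        hydrology=_apply_section(HydrologyParams, raw.get("hydrology", {}), "hydrology"),
        lc50_threshold=float(raw.get("lc50_threshold", 95.0)),
        random_seed=int(raw.get("random_seed", 0)),
        output_dir=raw.get("output_dir"),
        grid_output_cadence=int(raw.get("grid_output_cadence", 0)),
    )
    return cfg.validate()


def write_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    # YAML cannot round-trip tuples; lists re-enter the dataclasses fine.
    for sect in ("deposition", "contaminant", "hydrology"):
        for k, v in d[sect].items():
            if isinstance(v, tuple):
                d[sect][k] = list(v)
    with path.open("w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return path


def dry_season_mask(dates: pd.DatetimeIndex, dry_months: Iterable[int] = (6, 7, 8, 9)) -> np.ndarray:
    """True for days in the dry season (default June-September)."""
    months = set(dry_months)
    return np.array([d.month in months for d in dates])


def parse_date(s: str) -> _dt.date:
    return _dt.date.fromisoformat(s)
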