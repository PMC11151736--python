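"""Observables: pour-point concentration series, observed-sample comparison,
toxicity exceedance flags, hotspot maps, and mass-balance summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, CoverageError, DomainError
from .fate import MassBalanceLedger
from .grid_io import RasterGrid

#: Bundled observed grab samples at the pour point (ng/L).
OBSERVED_SAMPLES = pd.DataFrame(
    {
        "date": pd.to_datetime(
            ["2020-10-26", "2020-11-13", "2021-03-04", "2021-03-18", "2021-04-29"]
        ),
        "observed_ng_l": [6.63, 14.3, 27.4, 11.2, 1.71],
    }
)

#: Acute toxicity threshold for coho salmon, ng/L.
LC50_NG_L = 95.0


@dataclass
class PourPointSeries:
    """Daily pour-point discharge, load, and concentration."""

    frame: pd.DataFrame  # columns: date, discharge_m3, load_g, conc_ng_l, zero_flow

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def concentration_series(
    dates: Sequence,
    loads_g: np.ndarray,
    discharge_m3: np.ndarray,
) -> PourPointSeries:
    """Combine aligned daily load (g/day) and discharge (m^3/day) series.

    Concentration is load/discharge in g/m^3 scaled to ng/L (factor 1e6);
    zero-discharge days are reported as 0 ng/L and flagged."""
    dates = pd.DatetimeIndex(dates)
    loads_g = np.asarray(loads_g, dtype=float)
    discharge_m3 = np.asarray(discharge_m3, dtype=float)
    if not (len(dates) == len(loads_g) == len(discharge_m3)):
        raise AlignmentError("dates, loads and discharge must share one length")
    zero_flow = discharge_m3 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = np.where(zero_flow, 0.0, loads_g / np.where(zero_flow, 1.0, discharge_m3) * 1e6)
    return PourPointSeries(
        frame=pd.DataFrame(
            {
                "date": dates,
                "discharge_m3": discharge_m3,
                "load_g": loads_g,
                "conc_ng_l": conc,
                "zero_flow": zero_flow,
            }
        )
    )


def compare_observed(
    series: PourPointSeries,
    observed: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-date |simulated - observed| table and the maximum difference.

    Simulated values are daily averages; observed values are instantaneous
    grab samples, compared directly without sub-daily disaggregation."""
    if observed is None:
        observed = OBSERVED_SAMPLES
    sim = series.frame.set_index(pd.DatetimeIndex(series.frame["date"]))
    rows = []
    for _, rec in observed.iterrows():
        date = pd.Timestamp(rec["date"])
        if date < sim.index.min() or date > sim.index.max():
            raise CoverageError(f"observed date {date:%Y-%m-%d} outside simulated span")
        sim_val = float(sim.loc[date, "conc_ng_l"])
        obs_val = float(rec["observed_ng_l"])
        rows.append(
            {
                "date": date,
                "observed_ng_l": obs_val,
                "simulated_ng_l": sim_val,
                "abs_diff_ng_l": abs(sim_val - obs_val),
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["abs_diff_ng_l"].max())


def exceedance_flags(series: PourPointSeries, threshold_ng_l: float = LC50_NG_L) -> pd.DatetimeIndex:
    """Dates whose concentration meets or exceeds the threshold (inclusive)."""
    if threshold_ng_l <= 0:
        raise DomainError(f"threshold must be > 0, got {threshold_ng_l}")
    hit = series.frame["conc_ng_l"] >= threshold_ng_l
    return pd.DatetimeIndex(series.frame.loc[hit, "date"])


def hotspot_map(
    history: Iterable[tuple[pd.Timestamp, np.ndarray]],
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    stat: str = "mean",
    template: RasterGrid | None = None,
) -> RasterGrid | np.ndarray:
    """Per-cell time-mean (or time-max) mass over *window* from a history of
    (date, grid) pairs."""
    if stat not in ("mean", "max"):
        raise DomainError(f"stat must be 'mean' or 'max', got {stat!r}")
    acc = None
    count = 0
    for date, grid in history:
        date = pd.Timestamp(date)
        if window is not None and not (pd.Timestamp(window[0]) <= date <= pd.Timestamp(window[1])):
            continue
        arr = np.asarray(grid, dtype=float)
        if acc is None:
            acc = arr.copy()
        elif stat == "mean":
            acc += arr
        else:
            np.maximum(acc, arr, out=acc)
        count += 1
    if acc is None or count == 0:
        raise DomainError("empty hotspot window")
    if stat == "mean":
        acc /= count
    if template is not None:
        return template.copy_with(acc)
    return acc


def mass_balance_summary(ledger: MassBalanceLedger, storage_g: float) -> str:
    """Plain-text cumulative mass balance."""
    delta = storage_g - ledger.initial_storage_g
    residual = (
        ledger.deposited_g
        - ledger.decayed_g
        - ledger.stream_export_g
        - ledger.wwtp_export_g
        - ledger.boundary_export_g
        - delta
    )
    lines = [
        "Cumulative contaminant mass balance (g)",
        f"  deposited:       {ledger.deposited_g:.6e}",
        f"  decayed:         {ledger.decayed_g:.6e}",
        f"  stream export:   {ledger.stream_export_g:.6e}",
        f"  WWTP export:     {ledger.wwtp_export_g:.6e}",
        f"  boundary export: {ledger.boundary_export_g:.6e}",
        f"  storage change:  {delta:.6e}",
        f"  residual:        {residual:.3e}",
    ]
    return "\n".join(lines)
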