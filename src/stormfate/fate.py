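"""Contaminant fate: surface accumulation, wash-off, equilibrium sorption,
aqueous transport, first-order decay, and the mass-balance ledger.

Mass pools are stored as g/m^2 per cell (conversions to grams use the cell
area).  Sorbed mass is immobile; only aqueous mass advects, moving in
proportion to the fraction of a pool's water that moves.  Decay applies to
soil pools only and is modulated below optimal temperature and moisture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import ConservationError, DomainError, ValidationError
from .hydrology import HydrologyParams, SoilColumnState, SubsurfaceFluxes
from .watershed import IMPERVIOUS_CODES

if TYPE_CHECKING:  # pragma: no cover
    from .grid_io import RasterGrid


@dataclass
class ContaminantParams:
    """Contaminant constants.

    koc
        Organic-carbon-normalised soil adsorption coefficient, L/kg; the
        cell partition coefficient is Kd = koc * foc.
    molar_solubility / molar_mass
        mol/L and g/mol; their product is the mass solubility cap (g/L).
    max_decay
        First-order decay rate constant at optimal soil temperature and
        moisture, day^-1 (equivalently ln(2) / half-life of 3.14 days).
    log_kow
        Hydrophobicity metadata; only used when koc must be estimated,
        which this tool does not support (direct_koc must stay True).
    """

    koc: float = 11000.0
    molar_solubility: float = 0.000158
    molar_mass: float = 268.404
    max_decay: float = 0.2207475
    log_kow: float = 2.745
    direct_koc: bool = True
    q10: float = 2.0  # temperature sensitivity of the decay modulation
    t_opt_c: float = 25.0  # temperature at which decay runs at max_decay

    def validate(self) -> "ContaminantParams":
        for name in ("koc", "molar_solubility", "molar_mass", "max_decay"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.q10 <= 0:
            raise ValidationError(f"q10 must be > 0, got {self.q10}")
        if not self.direct_koc:
            raise NotImplementedError(
                "estimating koc from log_kow (direct_koc=False) is not supported; "
                "supply koc directly"
            )
        return self

    @property
    def solubility_g_per_l(self) -> float:
        """Mass solubility cap S = molar solubility x molar mass (g/L)."""
        return self.molar_solubility * self.molar_mass

    @property
    def half_life_days(self) -> float:
        return float(np.log(2.0) / self.max_decay)


@dataclass
class ContaminantState:
    """Per-cell contaminant pools (g/m^2): road-surface mass plus aqueous
    and sorbed mass in each of the four soil layers."""

    surface_g_m2: np.ndarray  # (nr, nc)
    aqueous_g_m2: np.ndarray  # (4, nr, nc)
    sorbed_g_m2: np.ndarray  # (4, nr, nc)

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "ContaminantState":
        return cls(
            surface_g_m2=np.zeros(shape),
            aqueous_g_m2=np.zeros((4, *shape)),
            sorbed_g_m2=np.zeros((4, *shape)),
        )

    def total_storage_g(self, cell_area: float) -> float:
        return float(
            (self.surface_g_m2.sum() + self.aqueous_g_m2.sum() + self.sorbed_g_m2.sum())
            * cell_area
        )

    def surface_storage_g(self, cell_area: float) -> float:
        return float(self.surface_g_m2.sum() * cell_area)

    def soil_storage_g(self, cell_area: float) -> float:
        return float((self.aqueous_g_m2.sum() + self.sorbed_g_m2.sum()) * cell_area)

    def check_nonnegative(self) -> None:
        if (
            np.any(self.surface_g_m2 < -1e-15)
            or np.any(self.aqueous_g_m2 < -1e-15)
            or np.any(self.sorbed_g_m2 < -1e-15)
        ):
            raise ConservationError("negative contaminant mass pool")


@dataclass
class MassBalanceLedger:
    """Cumulative grams in and out of the watershed since day one."""

    deposited_g: float = 0.0
    decayed_g: float = 0.0
    stream_export_g: float = 0.0
    wwtp_export_g: float = 0.0
    boundary_export_g: float = 0.0
    initial_storage_g: float = 0.0

    def residual(self, state: ContaminantState, cell_area: float) -> float:
        """|deposited - decayed - exports - delta storage| / max(deposited, eps)."""
        delta = state.total_storage_g(cell_area) - self.initial_storage_g
        imbalance = (
            self.deposited_g
            - self.decayed_g
            - self.stream_export_g
            - self.wwtp_export_g
            - self.boundary_export_g
            - delta
        )
        return abs(imbalance) / max(self.deposited_g, 1e-30)


def mass_balance_check(
    ledger: MassBalanceLedger,
    state: ContaminantState,
    cell_area: float,
    tolerance: float = 1e-9,
) -> float:
    """Return the relative residual; raise ConservationError above tolerance."""
    res = ledger.residual(state, cell_area)
    if res > tolerance:
        raise ConservationError(f"mass balance residual {res:.3e} exceeds {tolerance:.0e}")
    return res


def deposit(
    state: ContaminantState,
    deposition: "RasterGrid",
    ledger: MassBalanceLedger | None = None,
) -> ContaminantState:
    """Add the daily deposition grid to the road-surface pool."""
    values = deposition.values
    if values.shape != state.surface_g_m2.shape:
        raise DomainError("deposition grid shape mismatch")
    if np.any(values < 0):
        raise DomainError("negative deposition")
    state.surface_g_m2 += values
    if ledger is not None:
        ledger.deposited_g += float(values.sum()) * deposition.cell_area
    return state


def washoff(
    state: ContaminantState,
    runoff_mm: np.ndarray,
    land_cover: "RasterGrid",
    params: ContaminantParams,
) -> np.ndarray:
    """Dissolve surface mass into locally generated runoff on impervious
    cells, capped by solubility; returns the dissolved load grid (g) and
    removes it from the surface pool.  Residual mass stays on the surface."""
    area = land_cover.cell_area
    cover = land_cover.values.astype(int)
    impervious = np.isin(cover, IMPERVIOUS_CODES)
    runoff_l = np.maximum(np.asarray(runoff_mm, dtype=float), 0.0) * area  # mm * m^2 = L
    surface_g = state.surface_g_m2 * area
    capacity_g = params.solubility_g_per_l * runoff_l
    dissolved = np.where(impervious, np.minimum(surface_g, capacity_g), 0.0)
    state.surface_g_m2 -= dissolved / area
    return dissolved


def partition_layer(
    total_mass_g: float,
    water_volume_l: float,
    soil_mass_kg: float,
    foc: float,
    params: ContaminantParams,
) -> tuple[float, float]:
    """Equilibrium linear-isotherm split of *total_mass_g* into (aqueous,
    sorbed) grams.

    The aqueous concentration solves M = C*Vw + Kd*C*Ms with Kd = koc*foc
    (L/kg); the concentration is additionally capped at the solubility S
    with the excess held in the sorbed pool.
    """
    if min(total_mass_g, water_volume_l, soil_mass_kg, foc) < 0:
        raise DomainError("partition inputs must be non-negative")
    if total_mass_g == 0.0:
        return 0.0, 0.0
    kd = params.koc * foc
    denom = water_volume_l + kd * soil_mass_kg
    if denom == 0.0:
        raise DomainError("degenerate partition: no water and no soil but mass present")
    c = total_mass_g / denom
    c = min(c, params.solubility_g_per_l)
    aqueous = c * water_volume_l
    return aqueous, total_mass_g - aqueous


def partition_soil_column(
    state: ContaminantState,
    soil: SoilColumnState,
    foc_by_layer: tuple[float, float, float, float],
    hyd: HydrologyParams,
    params: ContaminantParams,
    cell_area: float,
) -> ContaminantState:
    """Re-equilibrate every soil layer of every cell (vectorised closed form
    of :func:`partition_layer`)."""
    thickness = np.asarray(hyd.layer_thickness_m)
    soil_mass_kg = hyd.bulk_density_kg_m3 * thickness * cell_area  # per layer
    s_cap = params.solubility_g_per_l
    for l in range(4):
        total_g = (state.aqueous_g_m2[l] + state.sorbed_g_m2[l]) * cell_area
        vw_l = soil.water_mm[l] * cell_area  # mm * m^2 = L
        kd = params.koc * foc_by_layer[l]
        denom = vw_l + kd * soil_mass_kg[l]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, total_g / np.where(denom > 0, denom, 1.0), 0.0)
        c = np.minimum(c, s_cap)
        aqueous_g = c * vw_l
        state.aqueous_g_m2[l] = aqueous_g / cell_area
        state.sorbed_g_m2[l] = (total_g - aqueous_g) / cell_area
    return state


def vertical_lateral_transport(
    state: ContaminantState,
    fluxes: SubsurfaceFluxes,
    ledger: MassBalanceLedger | None = None,
    cell_area: float = 25.0,
) -> ContaminantState:
    """Advect aqueous mass with the day's recorded soil-water movements.

    A layer losing fraction f of its water loses fraction f of its aqueous
    mass to the same destination; sorbed mass never moves.  Bottom-layer
    lateral mass follows the water split between storage at the successor
    and baseflow export to the stream."""
    aq = state.aqueous_g_m2
    for l in range(3):
        pre = fluxes.pre_perc_storage_mm[l]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(pre > 0, fluxes.percolation_mm[l] / np.where(pre > 0, pre, 1.0), 0.0)
        moved = aq[l] * frac
        aq[l] -= moved
        aq[l + 1] += moved

    pre4 = fluxes.pre_lateral_storage_mm
    lat = fluxes.lateral_out_mm
    nr, nc = lat.shape
    export = 0.0
    src = np.argwhere(lat > 0.0)
    if len(src):
        aq4 = aq[3]
        lat_flat = lat.ravel()
        stored_flat = fluxes.lateral_stored_mm.ravel()
        base_flat = fluxes.lateral_baseflow_mm.ravel()
        pre_flat = pre4.ravel()
        aq4_flat = aq4.ravel()
        moved_flat = np.zeros(nr * nc)
        for r, c in src:
            i = r * nc + c
            out = lat_flat[i]
            moved = aq4_flat[i] * out / pre_flat[i]
            moved_flat[i] = moved
        aq4_flat -= moved_flat
        for r, c in src:
            i = r * nc + c
            out = lat_flat[i]
            moved = moved_flat[i]
            if moved == 0.0:
                continue
            stored_share = moved * stored_flat[i] / out
            base_share = moved * base_flat[i] / out
            succ = int(fluxes.lateral_dest[i])
            if stored_share > 0.0 and succ >= 0:
                aq4_flat[succ] += stored_share
            export += base_share
        aq[3] = aq4_flat.reshape(nr, nc)
    if np.any(aq < -1e-15):
        raise ConservationError("negative aqueous mass after transport")
    if ledger is not None:
        ledger.stream_export_g += export * cell_area
    return state


def decay_modulators(
    tavg_c: float,
    soil: SoilColumnState,
    q10: float = 2.0,
    t_opt_c: float = 25.0,
) -> tuple[float, np.ndarray]:
    """Temperature and moisture decay modulation scalars in [0, 1].

    f_T = min(1, q10^((T - t_opt)/10)); f_W = min(1, theta/theta_fc) per
    layer and cell."""
    f_t = float(min(1.0, q10 ** ((tavg_c - t_opt_c) / 10.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_w = np.minimum(1.0, soil.water_mm / soil.field_capacity_mm[:, None, None])
    return f_t, f_w


def decay_step(
    state: ContaminantState,
    tavg_c: float,
    soil: SoilColumnState,
    params: ContaminantParams,
    ledger: MassBalanceLedger | None = None,
    cell_area: float = 25.0,
    q10: float = 2.0,
    t_opt_c: float = 25.0,
) -> ContaminantState:
    """First-order decay of every soil pool: survival exp(-k_max*f_T*f_W).

    Road-surface mass does not decay.  At optimal conditions the survival
    over one half-life (ln 2 / k_max = 3.14 days) is exactly one half."""
    f_t, f_w = decay_modulators(tavg_c, soil, q10=q10, t_opt_c=t_opt_c)
    if not 0.0 <= f_t <= 1.0 or np.any(f_w < 0) or np.any(f_w > 1):
        raise DomainError("decay modulation scalars must lie in [0, 1]")
    survive = np.exp(-params.max_decay * f_t * f_w)
    lost = (state.aqueous_g_m2 + state.sorbed_g_m2) * (1.0 - survive)
    state.aqueous_g_m2 *= survive
    state.sorbed_g_m2 *= survive
    if ledger is not None:
        ledger.decayed_g += float(lost.sum()) * cell_area
    return state
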