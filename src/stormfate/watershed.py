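"""Static spatial domain: terrain, land cover, soils, storm-sewer network,
and the derived flow field the simulator routes along.

Flow directions use the D8 scheme with the fixed neighbor order
E, SE, S, SW, W, NW, N, NE; ties go to the first maximal drop, which makes
routing deterministic across platforms.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, TopologyError, ValidationError
from .raster import RasterGrid

# Land-cover codes (documented in README).
ROAD = 1
ROOF = 2
OTHER_IMPERVIOUS = 3
PERVIOUS = 4
STREAM = 5
LANDCOVER_CODES = (ROAD, ROOF, OTHER_IMPERVIOUS, PERVIOUS, STREAM)
IMPERVIOUS_CODES = (ROAD, ROOF, OTHER_IMPERVIOUS)

# Neighbor offsets in tie-break order: E, SE, S, SW, W, NW, N, NE.
_NEIGHBOR_OFFSETS = (
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
)

TERMINAL = -1  # flow leaves the grid at this cell
WWTP = -2  # flow leaves the watershed to the treatment plant (CSS)


@dataclass(frozen=True)
class PipeLink:
    """One storm-drain link: surface water intercepted at ``inlet`` is
    delivered the same day to ``dest`` (MS4) or removed to the WWTP (CSS)."""

    inlet: tuple[int, int]
    dest: Optional[tuple[int, int]]  # None for CSS links
    system_type: str  # "MS4" | "CSS"

    def __post_init__(self) -> None:
        if self.system_type not in ("MS4", "CSS"):
            raise ValidationError(f"system_type must be MS4 or CSS, got {self.system_type!r}")
        if self.system_type == "MS4" and self.dest is None:
            raise ValidationError(f"MS4 link at {self.inlet} needs a destination cell")
        if self.system_type == "CSS" and self.dest is not None:
            raise ValidationError(f"CSS link at {self.inlet} must not have a destination")


@dataclass
class StormwaterNetwork:
    links: list[PipeLink] = field(default_factory=list)

    @property
    def inlets(self) -> list[tuple[int, int]]:
        return [link.inlet for link in self.links]

    def __len__(self) -> int:
        return len(self.links)


def read_network_csv(path: str | Path) -> StormwaterNetwork:
    """Network CSV columns: inlet_row, inlet_col, dest_row, dest_col
    (blank for CSS), system_type."""
    df = pd.read_csv(path)
    links = []
    for _, row in df.iterrows():
        sys_type = str(row["system_type"]).strip().upper()
        dest = None
        if sys_type == "MS4":
            dest = (int(row["dest_row"]), int(row["dest_col"]))
        links.append(
            PipeLink(inlet=(int(row["inlet_row"]), int(row["inlet_col"])), dest=dest, system_type=sys_type)
        )
    return StormwaterNetwork(links=links)


def write_network_csv(network: StormwaterNetwork, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for link in network.links:
        rows.append(
            {
                "inlet_row": link.inlet[0],
                "inlet_col": link.inlet[1],
                "dest_row": "" if link.dest is None else link.dest[0],
                "dest_col": "" if link.dest is None else link.dest[1],
                "system_type": link.system_type,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@dataclass
class FlowField:
    """Per-cell steepest-descent successors plus a topological order that
    visits every cell before its successor."""

    shape: tuple[int, int]
    direction: np.ndarray  # flat; index into neighbor order, TERMINAL at outlets
    downstream: np.ndarray  # flat successor index; TERMINAL at outlets
    topo_order: np.ndarray  # flat indices, upstream first
    cell_size: float

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]


def fill_pits(dem: RasterGrid, epsilon: float = 1e-6) -> RasterGrid:
    """Priority-flood pit filling with a strictly increasing epsilon along
    flats, so every cell gains a monotonically descending 8-neighbor path to
    the grid boundary.  Idempotent; never lowers a cell."""
    z = dem.values.copy()
    nr, nc = z.shape
    valid = dem.valid_mask
    if not valid.any():
        raise DomainError("DEM is all nodata")
    filled = np.full_like(z, np.inf)
    closed = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0

    def is_edge(r: int, c: int) -> bool:
        if r == 0 or c == 0 or r == nr - 1 or c == nc - 1:
            return True
        for dr, dc in _NEIGHBOR_OFFSETS:
            if not valid[r + dr, c + dc]:
                return True
        return False

    for r in range(nr):
        for c in range(nc):
            if valid[r, c] and is_edge(r, c):
                filled[r, c] = z[r, c]
                closed[r, c] = True
                heapq.heappush(heap, (z[r, c], counter, r, c))
                counter += 1
    while heap:
        elev, _, r, c = heapq.heappop(heap)
        for dr, dc in _NEIGHBOR_OFFSETS:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and valid[r2, c2] and not closed[r2, c2]:
                closed[r2, c2] = True
                filled[r2, c2] = max(z[r2, c2], elev + epsilon if z[r2, c2] <= elev else z[r2, c2])
                heapq.heappush(heap, (filled[r2, c2], counter, r2, c2))
                counter += 1
    out = z.copy()
    out[valid] = filled[valid]
    return dem.copy_with(out)


def _topological_order(downstream: np.ndarray, n: int) -> np.ndarray:
    indegree = np.zeros(n, dtype=np.int64)
    for succ in downstream:
        if succ >= 0:
            indegree[succ] += 1
    queue = deque(np.flatnonzero(indegree == 0).tolist())
    order = np.empty(n, dtype=np.int64)
    k = 0
    while queue:
        i = queue.popleft()
        order[k] = i
        k += 1
        succ = downstream[i]
        if succ >= 0:
            indegree[succ] -= 1
            if indegree[succ] == 0:
                queue.append(succ)
    if k != n:
        raise TopologyError("flow graph contains a cycle")
    return order


def compute_d8(dem: RasterGrid) -> FlowField:
    """Steepest-descent D8 directions on a pit-filled DEM.

    Drop is (elevation difference)/distance with diagonal distance
    cell_size*sqrt(2).  Boundary cells with no lower neighbor are terminals;
    an interior cell with no lower neighbor means the DEM was not pit-filled.
    """
    z = dem.values
    nr, nc = z.shape
    valid = dem.valid_mask
    zpad = np.full((nr + 2, nc + 2), np.nan)
    zpad[1:-1, 1:-1] = np.where(valid, z, np.nan)
    drops = np.full((8, nr, nc), -np.inf)
    for k, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        dist = dem.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        neigh = zpad[1 + dr : 1 + dr + nr, 1 + dc : 1 + dc + nc]
        with np.errstate(invalid="ignore"):
            d = (z - neigh) / dist
        drops[k] = np.where(np.isnan(neigh), -np.inf, d)
    best = np.argmax(drops, axis=0)  # first maximal drop wins (tie-break order)
    best_drop = np.take_along_axis(drops, best[None], axis=0)[0]
    direction = np.where(best_drop > 0, best, TERMINAL)
    direction[~valid] = TERMINAL

    # interior data cell with no positive drop => unresolved pit
    interior = np.zeros((nr, nc), dtype=bool)
    if nr > 2 and nc > 2:
        interior[1:-1, 1:-1] = True
    edge_adjacent = np.zeros((nr, nc), dtype=bool)
    for dr, dc in _NEIGHBOR_OFFSETS:
        neigh_valid = np.zeros((nr, nc), dtype=bool)
        rs = slice(max(0, dr), nr + min(0, dr))
        rd = slice(max(0, -dr), nr + min(0, -dr))
        cs = slice(max(0, dc), nc + min(0, dc))
        cd = slice(max(0, -dc), nc + min(0, -dc))
        neigh_valid[rd, cd] = valid[rs, cs]
        edge_adjacent |= ~neigh_valid
    pits = valid & interior & ~edge_adjacent & (best_drop <= 0)
    if pits.any():
        r, c = np.argwhere(pits)[0]
        raise TopologyError(f"unfilled pit at cell ({r}, {c}); run fill_pits first")

    downstream = np.full(nr * nc, TERMINAL, dtype=np.int64)
    flat_dir = direction.ravel()
    idx = np.arange(nr * nc)
    for k, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        sel = flat_dir == k
        downstream[sel] = idx[sel] + dr * nc + dc
    order = _topological_order(downstream, nr * nc)
    return FlowField(
        shape=(nr, nc),
        direction=flat_dir.copy(),
        downstream=downstream,
        topo_order=order,
        cell_size=dem.cell_size,
    )


def effective_downstream(flow: FlowField, network: StormwaterNetwork | None) -> np.ndarray:
    """D8 successors with pipe links spliced in: an MS4 inlet's successor is
    its outfall destination, a CSS inlet's successor is the WWTP sink."""
    nc = flow.shape[1]
    eff = flow.downstream.copy()
    if network is not None:
        for link in network.links:
            i = link.inlet[0] * nc + link.inlet[1]
            eff[i] = WWTP if link.dest is None else link.dest[0] * nc + link.dest[1]
    return eff


def effective_topo_order(flow: FlowField, network: StormwaterNetwork | None) -> np.ndarray:
    """Topological order over the pipe-spliced successor graph; raises
    TopologyError if a pipe creates a cycle."""
    eff = effective_downstream(flow, network)
    eff = np.where(eff == WWTP, TERMINAL, eff)
    return _topological_order(eff, flow.n_cells)


def delineate(
    flow: FlowField,
    pour_point: tuple[int, int],
    network: StormwaterNetwork | None = None,
    dem: RasterGrid | None = None,
) -> np.ndarray:
    """Boolean mask of cells whose successor chain reaches the pour point,
    with MS4 pipe links counting as successors from inlet to destination."""
    nr, nc = flow.shape
    pr, pc = pour_point
    if not (0 <= pr < nr and 0 <= pc < nc):
        raise DomainError(f"pour point {pour_point} outside grid {flow.shape}")
    if dem is not None and not dem.valid_mask[pr, pc]:
        raise DomainError(f"pour point {pour_point} is nodata")
    eff = effective_downstream(flow, network)
    # reverse adjacency, then BFS upstream from the pour point
    upstream: dict[int, list[int]] = {}
    for i, succ in enumerate(eff):
        if succ >= 0:
            upstream.setdefault(int(succ), []).append(i)
    target = pr * nc + pc
    mask = np.zeros(nr * nc, dtype=bool)
    mask[target] = True
    queue = deque([target])
    while queue:
        j = queue.popleft()
        for i in upstream.get(j, ()):
            if not mask[i]:
                mask[i] = True
                queue.append(i)
    return mask.reshape(nr, nc)


def upslope_of_inlet_mask(
    flow: FlowField,
    land_cover: RasterGrid,
    network: StormwaterNetwork,
) -> np.ndarray:
    """Road cells whose D8 successor chain, traversing only road cells,
    reaches a storm-drain inlet.  All other road cells (and all non-road
    impervious cells such as parking lots) are excluded."""
    nr, nc = flow.shape
    cover = land_cover.values.astype(int).ravel()
    road = cover == ROAD
    upstream: dict[int, list[int]] = {}
    for i, succ in enumerate(flow.downstream):
        if succ >= 0:
            upstream.setdefault(int(succ), []).append(i)
    mask = np.zeros(nr * nc, dtype=bool)
    queue: deque[int] = deque()
    for link in network.links:
        i = link.inlet[0] * nc + link.inlet[1]
        if road[i] and not mask[i]:
            mask[i] = True
            queue.append(i)
    while queue:
        j = queue.popleft()
        for i in upstream.get(j, ()):
            if road[i] and not mask[i]:
                mask[i] = True
                queue.append(i)
    return mask.reshape(nr, nc)


@dataclass
class NetworkReport:
    n_inlets: int
    n_ms4_outfalls: int
    n_css_links: int
    n_contributing_outfalls: int
    n_noncontributing_outfalls: int
    errors: list[str] = field(default_factory=list)


def validate_network(network: StormwaterNetwork, watershed: "Watershed") -> NetworkReport:
    """Count inlets/outfalls/CSS links and classify outfalls as upstream or
    downstream of the pour point; raises on duplicate inlets or off-grid
    destinations."""
    nr, nc = watershed.land_cover.shape
    seen: set[tuple[int, int]] = set()
    errors: list[str] = []
    for link in network.links:
        if link.inlet in seen:
            errors.append(f"duplicate inlet cell {link.inlet}")
        seen.add(link.inlet)
        r, c = link.inlet
        if not (0 <= r < nr and 0 <= c < nc):
            errors.append(f"inlet {link.inlet} off grid")
        if link.dest is not None:
            dr, dc = link.dest
            if not (0 <= dr < nr and 0 <= dc < nc):
                errors.append(f"MS4 destination {link.dest} off grid")
    if errors:
        raise ValidationError("; ".join(errors))

    contributing = delineate(watershed.flow, watershed.pour_point, network)
    ms4_dests = {link.dest for link in network.links if link.dest is not None}
    n_contrib = sum(1 for d in ms4_dests if contributing[d])
    return NetworkReport(
        n_inlets=len(network.links),
        n_ms4_outfalls=len(ms4_dests),
        n_css_links=sum(1 for link in network.links if link.system_type == "CSS"),
        n_contributing_outfalls=n_contrib,
        n_noncontributing_outfalls=len(ms4_dests) - n_contrib,
        errors=[],
    )


@dataclass
class Watershed:
    """The static simulation domain: grids, soils, network, and flow field."""

    dem: RasterGrid
    land_cover: RasterGrid
    traffic_count: RasterGrid
    network: StormwaterNetwork
    pour_point: tuple[int, int]
    flow: FlowField
    foc_by_layer: tuple[float, float, float, float] = (0.03, 0.01, 0.005, 0.002)

    def __post_init__(self) -> None:
        nr, nc = self.dem.shape
        if self.land_cover.shape != (nr, nc) or self.traffic_count.shape != (nr, nc):
            raise ValidationError("dem, land_cover and traffic_count shapes differ")
        pr, pc = self.pour_point
        if not (0 <= pr < nr and 0 <= pc < nc):
            raise ValidationError(f"pour point {self.pour_point} outside grid")
        foc = tuple(float(f) for f in self.foc_by_layer)
        if len(foc) != 4 or any(not 0 <= f <= 1 for f in foc):
            raise ValidationError("foc_by_layer must be 4 fractions in [0,1]")
        self.foc_by_layer = foc
        codes = set(np.unique(self.land_cover.values[self.land_cover.valid_mask]).astype(int))
        unknown = codes - set(LANDCOVER_CODES)
        if unknown:
            raise ValidationError(f"unknown land-cover codes {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dem.shape

    @property
    def cell_size(self) -> float:
        return self.dem.cell_size

    @property
    def cell_area(self) -> float:
        return self.dem.cell_area

    @property
    def pour_index(self) -> int:
        return self.pour_point[0] * self.shape[1] + self.pour_point[1]

    @classmethod
    def from_grids(
        cls,
        dem: RasterGrid,
        land_cover: RasterGrid,
        traffic_count: RasterGrid,
        network: StormwaterNetwork,
        pour_point: tuple[int, int],
        foc_by_layer: Sequence[float] = (0.03, 0.01, 0.005, 0.002),
        fill: bool = True,
    ) -> "Watershed":
        """Condition the DEM, derive the flow field, and assemble the domain."""
        conditioned = fill_pits(dem) if fill else dem
        flow = compute_d8(conditioned)
        effective_topo_order(flow, network)  # raises if pipes create a cycle
        return cls(
            dem=conditioned,
            land_cover=land_cover,
            traffic_count=traffic_count,
            network=network,
            pour_point=tuple(pour_point),
            flow=flow,
            foc_by_layer=tuple(foc_by_layer),
        )
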