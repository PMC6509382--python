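"""Kernel home ranges, utilization-distribution overlap, and site fidelity.

Each animal-season-year's utilization distribution (UD) is a fixed-kernel
density estimate: an isotropic bivariate normal kernel with the reference
bandwidth

    h_ref = sigma * n ** (-1/6),   sigma = sqrt((var(x) + var(y)) / 2),

evaluated on a regular grid and normalized to unit mass. The home range is
the 95 % isopleth: the smallest set of highest-density cells holding 95 %
of the mass. Pairwise overlap is the utilization distribution overlap
index

    UDOI = A_12 * integral( UD1(x, y) * UD2(x, y) ) dx dy,

with A_12 the intersection area of the two home ranges; UDOI is 0 for
disjoint ranges, 1 for identical uniform distributions, and can exceed 1
for strongly concentrated shared use. By default the UDs entering the
integral are conditioned on (restricted to and renormalized over) their
95 % home ranges; ``level=None`` selects the full-grid variant. UDOI edges
across a herd give the spatial network; within-animal cross-year UDOI for
the same season measures interannual site fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateBandwidthError,
    GridExtentError,
    InsufficientDataError,
)

MIN_FIXES = 5
ISOPLETH_LEVEL = 0.95


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: cell centres at origin + (i + 0.5) * cell."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return xs, ys


@dataclass
class UtilizationDistribution:
    grid: GridSpec
    pmass: np.ndarray  # (nx, ny) probability mass per cell, sums to 1
    h: float
    n_fixes: int


@dataclass(frozen=True)
class HomeRange:
    level: float
    area_km2: float
    mask: np.ndarray  # (nx, ny) member cells of the isopleth


@dataclass(frozen=True)
class FidelityRecord:
    animal_id: str
    herd: str
    season: str
    year_pair: tuple[int, int]
    udoi: float


def href_bandwidth(xy: np.ndarray) -> float:
    """Reference bandwidth sigma * n^(-1/6) for a bivariate normal kernel."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < MIN_FIXES:
        raise InsufficientDataError(f"need >= {MIN_FIXES} fixes, got {n}")
    xy = xy[np.lexsort((xy[:, 1], xy[:, 0]))]  # row-order invariance
    sigma = np.sqrt((xy[:, 0].var(ddof=1) + xy[:, 1].var(ddof=1)) / 2.0)
    if sigma == 0.0:
        raise DegenerateBandwidthError("all fixes coincide; bandwidth is zero")
    return float(sigma * n ** (-1.0 / 6.0))


def grid_for(
    points: np.ndarray,
    h: float,
    cell: float | None = None,
    margin: float | None = None,
) -> GridSpec:
    """Grid covering the points with a kernel-width margin.

    Defaults: cell = h/4, margin = 3h, which keeps truncated kernel mass
    negligible for fixes inside the bounding box.
    """
    points = np.asarray(points, dtype=float)
    cell = h / 4.0 if cell is None else cell
    margin = 3.0 * h if margin is None else margin
    x0 = points[:, 0].min() - margin
    y0 = points[:, 1].min() - margin
    nx = int(np.ceil((points[:, 0].max() + margin - x0) / cell))
    ny = int(np.ceil((points[:, 1].max() + margin - y0) / cell))
    return GridSpec(float(x0), float(y0), float(cell), nx, ny)


def estimate_ud(
    xy: np.ndarray,
    h: float | None = None,
    grid: GridSpec | None = None,
    max_truncation: float = 0.01,
) -> UtilizationDistribution:
    """Fixed-kernel UD of one animal's fixes on a regular grid.

    A bivariate normal kernel of bandwidth ``h`` (default: the reference
    bandwidth of the fixes) is centred on every fix, averaged, integrated
    over cells, and renormalized. Raises ``GridExtentError`` when more than
    ``max_truncation`` of the kernel mass falls outside the grid.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < MIN_FIXES:
        raise InsufficientDataError(f"need >= {MIN_FIXES} fixes, got {len(xy)}")
    # canonical fix order: the estimate is invariant to row order bit-for-bit
    xy = xy[np.lexsort((xy[:, 1], xy[:, 0]))]
    if h is None:
        h = href_bandwidth(xy)
    if h <= 0:
        raise DegenerateBandwidthError("bandwidth must be positive")
    if grid is None:
        grid = grid_for(xy, h)
    xs, ys = grid.centers()
    # separable kernel: density[i, j] = sum_k ax[i, k] * ay[j, k]
    ax = np.exp(-((xs[:, None] - xy[None, :, 0]) ** 2) / (2.0 * h * h))
    ay = np.exp(-((ys[:, None] - xy[None, :, 1]) ** 2) / (2.0 * h * h))
    dens = ax @ ay.T  # unnormalized density at cell centres
    mass = dens * grid.cell_area / (2.0 * np.pi * h * h * len(xy))
    total = float(mass.sum())
    if total < 1.0 - max_truncation:
        raise GridExtentError(
            f"grid truncates {1 - total:.1%} of kernel mass (> {max_truncation:.0%})"
        )
    return UtilizationDistribution(grid=grid, pmass=mass / total, h=float(h), n_fixes=len(xy))


def isopleth(ud: UtilizationDistribution, level: float = ISOPLETH_LEVEL) -> HomeRange:
    """Smallest highest-density cell set holding ``level`` of the mass."""
    flat = ud.pmass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    k = min(k, len(flat))
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.pmass.shape)
    area_km2 = float(mask.sum()) * ud.grid.cell_area / 1e6
    return HomeRange(level=level, area_km2=area_km2, mask=mask)


def _conditioned(ud: UtilizationDistribution, level: float | None):
    if level is None:  # full-grid variant: the home range is the UD support
        return ud.pmass, ud.pmass > 0
    mask = isopleth(ud, level).mask
    p = np.where(mask, ud.pmass, 0.0)
    return p / p.sum(), mask


def udoi(
    ud1: UtilizationDistribution,
    ud2: UtilizationDistribution,
    level: float | None = ISOPLETH_LEVEL,
) -> float:
    """Utilization distribution overlap index of two UDs on a common grid."""
    if ud1.grid != ud2.grid:
        raise AlignmentError("UDs are not on a common grid")
    p1, m1 = _conditioned(ud1, level)
    p2, m2 = _conditioned(ud2, level)
    inter_area = float((m1 & m2).sum()) * ud1.grid.cell_area
    if inter_area == 0.0:
        return 0.0
    integral = float((p1 * p2).sum()) / ud1.grid.cell_area
    return inter_area * integral


def build_spatial_network(
    uds: dict[str, UtilizationDistribution], level: float | None = ISOPLETH_LEVEL
) -> nx.Graph:
    """Complete UDOI-weighted network over one herd-season-year's UDs."""
    graph = nx.Graph()
    ids = sorted(uds)
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            graph.add_edge(a, b, weight=udoi(uds[a], uds[b], level=level))
    for node in graph.nodes:
        graph.nodes[node]["strength"] = float(
            sum(d["weight"] for _, _, d in graph.edges(node, data=True))
        )
    return graph


def seasonal_uds(
    fixes: pd.DataFrame,
    cell: float | None = None,
    min_fixes: int = MIN_FIXES,
) -> dict[tuple, dict[str, UtilizationDistribution]]:
    """UDs per (herd, season, year), each group sharing one grid.

    The shared grid covers every animal of the group (bandwidths are still
    per-animal) so that pairwise UDOI is defined without resampling.
    Animal-season-years with fewer than ``min_fixes`` fixes are skipped.
    """
    out: dict[tuple, dict[str, UtilizationDistribution]] = {}
    for key, sub in fixes.groupby(["herd", "season", "year"], sort=True):
        tracks = {
            a: t[["x", "y"]].to_numpy(float)
            for a, t in sub.groupby("animal_id", sort=True)
            if len(t) >= min_fixes
        }
        hs = {}
        for a, xy in list(tracks.items()):
            try:
                hs[a] = href_bandwidth(xy)
            except DegenerateBandwidthError:
                del tracks[a]
        if not tracks:
            continue
        hmax = max(hs.values())
        pts = np.vstack(list(tracks.values()))
        grid = grid_for(pts, hmax, cell=cell)
        out[key] = {a: estimate_ud(xy, hs[a], grid) for a, xy in tracks.items()}
    return out


def home_range_table(
    uds: dict[tuple, dict[str, UtilizationDistribution]],
    level: float = ISOPLETH_LEVEL,
) -> pd.DataFrame:
    """Long table of 95 % home-range areas (km^2) per animal-season-year."""
    rows = [
        {
            "herd": h,
            "season": s,
            "year": y,
            "animal_id": a,
            "hr_area_km2": isopleth(ud, level).area_km2,
        }
        for (h, s, y), group in uds.items()
        for a, ud in group.items()
    ]
    return pd.DataFrame(
        rows, columns=["herd", "season", "year", "animal_id", "hr_area_km2"]
    )


def site_fidelity(
    fixes: pd.DataFrame,
    cell: float | None = None,
    level: float | None = ISOPLETH_LEVEL,
    min_fixes: int = MIN_FIXES,
) -> list[FidelityRecord]:
    """Within-animal cross-year UDOI for each season and consecutive year pair.

    For every animal-season with valid UDs in years Y and Y+1, both years'
    UDs are re-estimated on one shared grid and their UDOI recorded.
    Non-consecutive year pairs yield no record.
    """
    records: list[FidelityRecord] = []
    for (animal, herd, season), sub in fixes.groupby(
        ["animal_id", "herd", "season"], sort=True
    ):
        by_year = {
            int(y): t[["x", "y"]].to_numpy(float)
            for y, t in sub.groupby("year")
            if len(t) >= min_fixes
        }
        for y in sorted(by_year):
            if y + 1 not in by_year:
                continue
            a, b = by_year[y], by_year[y + 1]
            try:
                ha, hb = href_bandwidth(a), href_bandwidth(b)
            except DegenerateBandwidthError:
                continue
            grid = grid_for(np.vstack([a, b]), max(ha, hb), cell=cell)
            rec = udoi(
                estimate_ud(a, ha, grid), estimate_ud(b, hb, grid), level=level
            )
            records.append(FidelityRecord(animal, herd, season, (y, y + 1), float(rec)))
    return records


def fidelity_table(records: list[FidelityRecord]) -> pd.DataFrame:
    rows = [
        {
            "animal_id": r.animal_id,
            "herd": r.herd,
            "season": r.season,
            "year_pair": f"{r.year_pair[0]}-{r.year_pair[1]}",
            "udoi": r.udoi,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["animal_id", "herd", "season", "year_pair", "udoi"]
    )
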