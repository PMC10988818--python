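"""Seasonal utilization distributions, core-area contours and overlap.

Space use is summarized per species and 2-month seasonal window (the
windows run Sep-Oct, Nov-Dec, Jan-Feb, Mar-Apr, May-Jun, Jul-Aug) as a
kernel utilization distribution (UD) on a regular lon-lat grid: an
isotropic Gaussian kernel in degree space with bandwidth h = 2.25°
(≈ 250 km at these latitudes), evaluated per individual on a 0.25° grid
and rescaled to sum to one, then averaged across individuals.  Core areas
are the smallest sets of cells holding 50% (or 75%) of the UD mass, and
between-species overlap is the fraction of one species' core area also in
the other's (cos(latitude)-weighted cell areas; raster masks, not
polygons).  The breeding-synchronization counterfactual shifts one
species' timestamps by two calendar months and reruns the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from petrelwind.geo import KM_PER_DEG

#: 2-month windows in pipeline order, as tuples of calendar months.
WINDOWS: tuple[tuple[int, int], ...] = ((9, 10), (11, 12), (1, 2), (3, 4), (5, 6), (7, 8))
WINDOW_NAMES = ("Sep-Oct", "Nov-Dec", "Jan-Feb", "Mar-Apr", "May-Jun", "Jul-Aug")

_MONTH_TO_WINDOW = {m: i for i, pair in enumerate(WINDOWS) for m in pair}


@dataclass
class UDGrid:
    """Normalized utilization density on a regular lon-lat grid."""

    density: np.ndarray  # (lat, lon), sums to 1
    lon: np.ndarray  # cell-centre longitudes
    lat: np.ndarray
    h_deg: float
    species: str | None = None
    window: str | None = None
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("UD density must be non-negative")
        s = self.density.sum()
        if s <= 0:
            raise ValueError("UD density is identically zero")
        self.density = self.density / s

    @property
    def cell_area_km2(self) -> np.ndarray:
        """(lat, lon) grid of cell areas, cos(lat)-weighted."""
        res_lon = np.diff(self.lon).mean() if self.lon.size > 1 else 0.25
        res_lat = np.diff(self.lat).mean() if self.lat.size > 1 else 0.25
        a = (KM_PER_DEG * res_lat) * (KM_PER_DEG * res_lon) * np.cos(np.radians(self.lat))
        return np.broadcast_to(a[:, None], self.density.shape)


def make_grid(
    lon_min: float, lon_max: float, lat_min: float, lat_max: float, res: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinate vectors for a regular lon-lat grid."""
    lon = np.arange(np.floor(lon_min / res) * res, lon_max + res, res) + res / 2
    lat = np.arange(np.floor(lat_min / res) * res, lat_max + res, res) + res / 2
    return lon, lat


def seasonal_windows(locations: pd.DataFrame, date_col: str = "date") -> dict[str, pd.DataFrame]:
    """Split locations into the six 2-month windows by calendar month."""
    months = pd.to_datetime(locations[date_col]).dt.month
    out = {}
    for i, name in enumerate(WINDOW_NAMES):
        out[name] = locations[months.map(_MONTH_TO_WINDOW) == i]
    return out


def kernel_ud(
    points: pd.DataFrame,
    grid: tuple[np.ndarray, np.ndarray],
    h_deg: float = 2.25,
    species: str | None = None,
    window: str | None = None,
) -> UDGrid:
    """Gaussian-kernel UD of one individual's points on a shared grid.

    The kernel is isotropic in degree space with standard deviation
    ``h_deg`` per axis; the evaluated grid is renormalized so the cell
    values sum to exactly one.
    """
    if len(points) < 1:
        raise ValueError("kernel_ud needs at least one point")
    if h_deg <= 0:
        raise ValueError("bandwidth must be positive")
    lon, lat = grid
    px = points["lon"].to_numpy(dtype=float)
    py = points["lat"].to_numpy(dtype=float)
    # separable Gaussian: (n, lon) and (n, lat) factors
    gx = np.exp(-0.5 * ((lon[None, :] - px[:, None]) / h_deg) ** 2)
    gy = np.exp(-0.5 * ((lat[None, :] - py[:, None]) / h_deg) ** 2)
    dens = gy.T @ gx  # (lat, lon)
    return UDGrid(density=dens, lon=lon, lat=lat, h_deg=h_deg, species=species, window=window)


def mean_ud(uds: list[UDGrid]) -> UDGrid:
    """Mean UD across individuals (then renormalized to sum 1)."""
    if not uds:
        raise ValueError("no UDs to average")
    ref = uds[0]
    for u in uds[1:]:
        if u.density.shape != ref.density.shape:
            raise ValueError("UDs must share a grid")
    dens = np.mean([u.density for u in uds], axis=0)
    return UDGrid(
        density=dens,
        lon=ref.lon,
        lat=ref.lat,
        h_deg=ref.h_deg,
        species=ref.species,
        window=ref.window,
        n_individuals=len(uds),
    )


def species_window_ud(
    locations: pd.DataFrame,
    grid: tuple[np.ndarray, np.ndarray],
    h_deg: float = 2.25,
    species: str | None = None,
    window: str | None = None,
    id_col: str = "bird_id",
) -> UDGrid:
    """Per-individual UDs averaged into one species-window UD."""
    uds = [
        kernel_ud(g, grid, h_deg=h_deg, species=species, window=window)
        for _, g in locations.groupby(id_col)
        if len(g)
    ]
    return mean_ud(uds)


def ud_contour(ud: UDGrid, level: float) -> np.ndarray:
    """Smallest set of cells holding ``level`` of the UD mass.

    Cells are ranked by density and accumulated until the cumulative mass
    reaches the level; returns a boolean (lat, lon) mask.  By
    construction the 50% set is nested inside the 75% set.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape)


def contour_area_km2(ud: UDGrid, level: float) -> float:
    mask = ud_contour(ud, level)
    return float(ud.cell_area_km2[mask].sum())


def contour_polygons(ud: UDGrid, level: float):
    """Contour mask as a shapely (multi)polygon of merged cell boxes."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    mask = ud_contour(ud, level)
    res_lon = np.diff(ud.lon).mean() if ud.lon.size > 1 else 0.25
    res_lat = np.diff(ud.lat).mean() if ud.lat.size > 1 else 0.25
    cells = [
        box(ud.lon[j] - res_lon / 2, ud.lat[i] - res_lat / 2, ud.lon[j] + res_lon / 2, ud.lat[i] + res_lat / 2)
        for i, j in zip(*np.nonzero(mask))
    ]
    return unary_union(cells)


@dataclass
class OverlapResult:
    """Directional core-area overlap between two species in one window."""

    window: str | None
    level: float
    proportion_a_in_b: float
    proportion_b_in_a: float
    scenario: str = "observed"


def overlap(ud_a: UDGrid, ud_b: UDGrid, level: float = 0.5, scenario: str = "observed") -> OverlapResult:
    """Fraction of each species' core area lying inside the other's.

    Computed on the contour masks with cos(lat)-weighted cell areas;
    directional, so A-in-B and B-in-A generally differ.
    """
    if ud_a.density.shape != ud_b.density.shape:
        raise ValueError("UDs must share a grid")
    ma = ud_contour(ud_a, level)
    mb = ud_contour(ud_b, level)
    area = ud_a.cell_area_km2
    inter = float(area[ma & mb].sum())
    return OverlapResult(
        window=ud_a.window,
        level=level,
        proportion_a_in_b=inter / float(area[ma].sum()),
        proportion_b_in_a=inter / float(area[mb].sum()),
        scenario=scenario,
    )


def synchronize_phenology(locations: pd.DataFrame, shift_months: int = 2, date_col: str = "date") -> pd.DataFrame:
    """Shift timestamps by whole calendar months (day clamped to month end).

    Adding two months to one species' data aligns its breeding cycle with
    the other's; 31 Dec + 2 months clamps to 28/29 Feb.
    """
    out = locations.copy()
    out[date_col] = pd.to_datetime(out[date_col]) + pd.DateOffset(months=shift_months)
    return out


def yearly_overlap_table(
    locs_a: pd.DataFrame,
    locs_b: pd.DataFrame,
    grid: tuple[np.ndarray, np.ndarray],
    h_deg: float = 2.25,
    levels: tuple[float, ...] = (0.5, 0.75),
    scenario: str = "observed",
    species: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Window × level overlap table for two species' location sets."""
    wa = seasonal_windows(locs_a)
    wb = seasonal_windows(locs_b)
    rows = []
    for name in WINDOW_NAMES:
        if len(wa[name]) == 0 or len(wb[name]) == 0:
            continue
        ua = species_window_ud(wa[name], grid, h_deg=h_deg, species=species[0], window=name)
        ub = species_window_ud(wb[name], grid, h_deg=h_deg, species=species[1], window=name)
        for level in levels:
            r = overlap(ua, ub, level=level, scenario=scenario)
            rows.append(
                {
                    "window": name,
                    "level": level,
                    "scenario": scenario,
                    f"prop_{species[0]}_in_{species[1]}": r.proportion_a_in_b,
                    f"prop_{species[1]}_in_{species[0]}": r.proportion_b_in_a,
                }
            )
    return pd.DataFrame(rows)
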