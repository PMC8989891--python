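"""Marginal-land extraction and latitude-corrected area accounting.

The mean suitability map is thresholded (default 0.5, ties suitable), masked
to the land-cover classes considered marginal (woody savannas, savannas,
closed and open shrublands, grasslands), and tabulated into hectares by zone
and class using spherical cell areas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import EARTH_RADIUS_KM, GridSpec, Raster

__all__ = [
    "MARGINAL_CLASSES",
    "LandUseMap",
    "threshold_suitability",
    "mask_by_landuse",
    "cell_area_ha",
    "row_areas_ha",
    "tabulate_areas",
]

logger = logging.getLogger(__name__)

#: Land-cover class names considered marginal (available for energy crops).
MARGINAL_CLASSES = (
    "woody_savannas",
    "savannas",
    "closed_shrublands",
    "open_shrublands",
    "grasslands",
)


@dataclass
class LandUseMap:
    """Integer-coded land-cover raster with a class legend."""

    raster: Raster
    classes: dict[int, str]
    allowed: tuple[str, ...] = MARGINAL_CLASSES

    def __post_init__(self) -> None:
        vals = self.raster.values
        present = np.unique(vals[self.raster.valid]).astype(int)
        unknown = [int(c) for c in present if int(c) not in self.classes]
        if unknown:
            logger.warning("land-use codes without legend entries: %s", unknown)

    @property
    def allowed_codes(self) -> tuple[int, ...]:
        return tuple(code for code, name in self.classes.items() if name in self.allowed)


def threshold_suitability(mean_map: Raster, threshold: float = 0.5) -> Raster:
    """Boolean suitability raster: True iff value >= threshold (ties suitable).

    NoData cells are False.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be within [0, 1]")
    vals = np.asarray(mean_map.values, dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("suitability map must lie in [0, 1]")
    suitable = (vals >= threshold) & mean_map.valid
    return Raster(suitable, mean_map.grid, name="suitable", nodata=-1, categorical=True)


def mask_by_landuse(
    suitable: Raster, landuse: LandUseMap, allowed: tuple[str, ...] | None = None
) -> Raster:
    """Marginal-land raster: land-use code where suitable and allowed, else NoData."""
    lu = landuse.raster
    if lu.grid != suitable.grid:
        raise ValueError("suitability and land-use rasters are on different grids")
    allowed = allowed if allowed is not None else landuse.allowed
    codes = tuple(code for code, name in landuse.classes.items() if name in allowed)
    keep = (
        np.asarray(suitable.values, dtype=bool)
        & lu.valid
        & np.isin(lu.values, codes)
    )
    vals = np.where(keep, lu.values, -9999).astype(int)
    return Raster(vals, lu.grid, name="marginal_land", nodata=-9999, categorical=True)


def cell_area_ha(lat_north_edge: float, lat_south_edge: float, resolution_deg: float) -> float:
    """Spherical area (hectares) of one grid cell.

    ``A = R^2 * dlambda * (sin(phi_N) - sin(phi_S))`` with the mean Earth
    radius R = 6371.0088 km; 1 km^2 = 100 ha.
    """
    if abs(lat_north_edge) > 90 or abs(lat_south_edge) > 90:
        raise ValueError("latitudes must lie within [-90, 90]")
    if lat_north_edge <= lat_south_edge:
        raise ValueError("north edge must be above south edge")
    dlam = math.radians(resolution_deg)
    area_km2 = (
        EARTH_RADIUS_KM**2
        * dlam
        * (math.sin(math.radians(lat_north_edge)) - math.sin(math.radians(lat_south_edge)))
    )
    return area_km2 * 100.0


def row_areas_ha(grid: GridSpec) -> np.ndarray:
    """Cell area per grid row (constant along a row), length ``rows``."""
    north, south = grid.lat_edges(np.arange(grid.rows))
    dlam = math.radians(grid.resolution_deg)
    area_km2 = EARTH_RADIUS_KM**2 * dlam * (np.sin(np.radians(north)) - np.sin(np.radians(south)))
    return area_km2 * 100.0


def tabulate_areas(
    marginal: Raster,
    classes: dict[int, str],
    zones: Raster | None = None,
    zone_names: dict[int, str] | None = None,
    flat_count_ha: float | None = None,
) -> pd.DataFrame:
    """Cross-tabulate marginal-land hectares by zone and land-use class.

    Returns a long-format table ``zone, landuse, hectares, percent`` plus a
    ``__total__`` row per zone and a global ``__total__`` zone; ``percent``
    is each class's share of the grand total (two-decimal reporting is left
    to the caller). ``flat_count_ha`` switches from spherical cell areas to a
    fixed nominal area per cell (e.g. 2500 ha for a 5 x 5 km cell).

    An empty marginal raster yields an all-zero table with percentages 0 and
    a warning.
    """
    grid = marginal.grid
    if zones is not None and zones.grid != grid:
        raise ValueError("zone raster grid mismatch")
    if flat_count_ha is not None:
        areas = np.full(grid.shape, float(flat_count_ha))
    else:
        areas = np.broadcast_to(row_areas_ha(grid)[:, None], grid.shape)
    valid = marginal.valid
    if zones is None:
        zone_vals = np.where(valid, 1, -9999)
        zone_names = {1: "global"}
    else:
        zone_vals = zones.values
        zone_names = zone_names or {
            int(z): f"zone_{int(z)}" for z in np.unique(zones.values[zones.valid])
        }
    mask = valid & (zone_vals != -9999)
    records: dict[tuple[int, int], float] = {}
    if mask.any():
        z = zone_vals[mask].astype(int)
        c = marginal.values[mask].astype(int)
        a = areas[mask]
        df = pd.DataFrame({"zone": z, "code": c, "ha": a})
        grouped = df.groupby(["zone", "code"])["ha"].sum()
        records = grouped.to_dict()
    else:
        logger.warning("marginal raster is empty; area table is all zero")
    rows = []
    grand_total = float(sum(records.values()))
    class_totals: dict[int, float] = {}
    for (z, c), ha in records.items():
        class_totals[c] = class_totals.get(c, 0.0) + ha
    for zone_code, zname in sorted(zone_names.items()):
        ztotal = 0.0
        for code in sorted(classes):
            ha = float(records.get((zone_code, code), 0.0))
            ztotal += ha
            rows.append((zname, classes[code], ha, np.nan))
        rows.append((zname, "__total__", ztotal, np.nan))
    for code in sorted(classes):
        ha = class_totals.get(code, 0.0)
        pct = 100.0 * ha / grand_total if grand_total > 0 else 0.0
        rows.append(("__total__", classes[code], ha, pct))
    rows.append(("__total__", "__total__", grand_total,
                 100.0 if grand_total > 0 else 0.0))
    return pd.DataFrame(rows, columns=["zone", "landuse", "hectares", "percent"])


def composition_percentages(class_hectares: dict[str, float]) -> dict[str, float]:
    """Class shares of the grand total, in percent (two decimals)."""
    total = sum(class_hectares.values())
    if total <= 0:
        logger.warning("zero total area; composition undefined, reporting 0")
        return {k: 0.0 for k in class_hectares}
    return {k: round(100.0 * v / total, 2) for k, v in class_hectares.items()}


__all__.append("composition_percentages")
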