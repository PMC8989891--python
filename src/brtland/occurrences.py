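"""Occurrence gridding, climatic-envelope pseudo-absence sampling, covariate extraction.

Raw presence-only records (e.g. a GBIF download) are aggregated to grid
cells at the analysis resolution; pseudo-absences are drawn uniformly from
cells whose climate falls outside the species' broad tolerance envelope; and
covariate values are read at each selected cell to build the model's design
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import EnvStack, GridSpec, Raster

__all__ = [
    "EnvelopeRule",
    "grid_occurrences",
    "envelope_mask",
    "sample_pseudo_absences",
    "extract_covariates",
    "build_cell_table",
    "CATEGORICAL_COVARIATES",
]

logger = logging.getLogger(__name__)

#: Covariates treated as categorical in the design table.
CATEGORICAL_COVARIATES = ("soil_class",)


@dataclass(frozen=True)
class EnvelopeRule:
    """Climatic envelope of broad unsuitability used for background sampling.

    A cell is background-eligible when its mean annual temperature falls
    outside ``[temp_low, temp_high]`` (deg C) or its annual precipitation
    outside ``[precip_low, precip_high]`` (mm). ``logic='and'`` requires both
    axes to disqualify.
    """

    temp_low: float = 5.8
    temp_high: float = 28.4
    precip_low: float = 400.0
    precip_high: float = 1900.0
    logic: str = "or"
    temp_layer: str = "temperature"
    precip_layer: str = "precipitation"

    def __post_init__(self) -> None:
        if not self.temp_low < self.temp_high:
            raise ValueError("temp_low must be < temp_high")
        if not self.precip_low < self.precip_high:
            raise ValueError("precip_low must be < precip_high")
        if self.logic not in ("or", "and"):
            raise ValueError("logic must be 'or' or 'and'")


def grid_occurrences(points: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Aggregate occurrence points to the distinct grid cells containing them.

    Parameters
    ----------
    points : DataFrame with ``lon`` and ``lat`` columns.
    grid : analysis grid.

    Returns
    -------
    DataFrame with one row per occupied cell: ``cell_id, row, col``
    (``cell_id = row * cols + col``), sorted by cell_id. Points outside the
    grid are dropped (count logged).
    """
    if len(points) == 0:
        raise ValueError("no occurrence points supplied")
    lon = np.asarray(points["lon"], dtype=float)
    lat = np.asarray(points["lat"], dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("occurrence coordinates must be finite")
    row, col = grid.cell_of(lon, lat)
    keep = grid.inside(row, col)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d occurrence points outside the grid", n_dropped)
    if not keep.any():
        raise ValueError("all occurrence points fall outside the grid")
    cell_id = row[keep] * grid.cols + col[keep]
    uniq = np.unique(cell_id)
    return pd.DataFrame(
        {"cell_id": uniq, "row": uniq // grid.cols, "col": uniq % grid.cols}
    )


def envelope_mask(stack: EnvStack, rule: EnvelopeRule = EnvelopeRule()) -> Raster:
    """Boolean raster of cells outside the species' climatic envelope.

    NoData cells (in the temperature or precipitation layer) are False.
    """
    temp = stack[rule.temp_layer]
    precip = stack[rule.precip_layer]
    t, p = temp.values, precip.values
    t_out = (t < rule.temp_low) | (t > rule.temp_high)
    p_out = (p < rule.precip_low) | (p > rule.precip_high)
    out = (t_out | p_out) if rule.logic == "or" else (t_out & p_out)
    out &= temp.valid & precip.valid
    return Raster(out, stack.grid, name="envelope", nodata=-1, categorical=True)


def sample_pseudo_absences(
    mask: Raster, presence_cells: pd.DataFrame, n: int, seed: int
) -> pd.DataFrame:
    """Sample ``n`` background cells uniformly without replacement.

    Eligible cells are True in ``mask`` and not presence cells. Raises with
    the shortfall named if fewer than ``n`` cells are eligible.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    grid = mask.grid
    eligible = np.flatnonzero(np.asarray(mask.values, dtype=bool).ravel())
    eligible = np.setdiff1d(eligible, presence_cells["cell_id"].to_numpy(), assume_unique=False)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible background cells for {n} requested "
            f"(short by {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=n, replace=False))
    return pd.DataFrame(
        {"cell_id": chosen, "row": chosen // grid.cols, "col": chosen % grid.cols}
    )


def extract_covariates(cells: pd.DataFrame, stack: EnvStack) -> pd.DataFrame:
    """Read every stack layer at each cell; drop rows with any NoData.

    Returns the input frame with one column per layer appended; categorical
    layers keep integer codes. The number of dropped rows is logged.
    """
    rows = cells["row"].to_numpy()
    cols = cells["col"].to_numpy()
    if not (stack.grid.inside(rows, cols)).all():
        raise ValueError("cells outside the stack grid")
    out = cells.reset_index(drop=True).copy()
    keep = np.ones(len(out), dtype=bool)
    for name, layer in stack.layers.items():
        out[name] = layer.values[rows, cols]
        keep &= layer.valid[rows, cols]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d cells with NoData covariates", n_dropped)
    return out[keep].reset_index(drop=True)


def build_cell_table(
    points: pd.DataFrame,
    stack: EnvStack,
    rule: EnvelopeRule = EnvelopeRule(),
    seed: int = 0,
    n_absences: int | None = None,
) -> pd.DataFrame:
    """End-to-end design table: presences, matched pseudo-absences, covariates.

    Presence points are gridded and labelled 1; an equal number of
    envelope-constrained pseudo-absence cells (labelled 0) is sampled unless
    ``n_absences`` overrides the 1:1 default. Cells with missing covariates
    are dropped *before* balancing so the label counts refer to modelled rows.
    """
    presences = extract_covariates(grid_occurrences(points, stack.grid), stack)
    presences.insert(3, "label", 1)
    if n_absences is None:
        n_absences = len(presences)
    mask = envelope_mask(stack, rule)
    absences = sample_pseudo_absences(mask, presences, n_absences, seed)
    absences = extract_covariates(absences, stack)
    absences.insert(3, "label", 0)
    table = pd.concat([presences, absences], ignore_index=True)
    assert not set(presences["cell_id"]) & set(absences["cell_id"])
    return table
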