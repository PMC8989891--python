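"""Synthetic landscapes with known structure for testing the pipeline.

Generates the inputs a real study would download — a nine-layer
environmental covariate stack (climate, soil, topography), a categorical
land-cover map, presence records, and aggregation zones — with the
statistical features the analysis relies on: spatial autocorrelation
(Gaussian-smoothed noise), a north–south temperature gradient so the
climatic envelope partitions the map spatially, a NoData "ocean" border,
latitude spans wide enough that spherical cell areas vary, and a known true
suitability surface so parameter recovery can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import rankdata

from .occurrences import EnvelopeRule
from .raster import EnvStack, GridSpec, Raster

__all__ = [
    "LayerSpec",
    "SyntheticConfig",
    "generate_env_stack",
    "true_suitability",
    "sample_occurrences",
    "generate_landuse",
    "generate_zones",
    "DEFAULT_COVARIATES",
    "IGBP_CLASSES",
]

#: IGBP-style land-cover legend (the subset the analysis touches).
IGBP_CLASSES = {
    2: "evergreen_broadleaf_forest",
    6: "closed_shrublands",
    7: "open_shrublands",
    8: "woody_savannas",
    9: "savannas",
    10: "grasslands",
    12: "croplands",
    16: "barren",
}


@dataclass(frozen=True)
class LayerSpec:
    """Range and spatial smoothness (Gaussian sigma, in cells) of one layer."""

    low: float
    high: float
    sigma_cells: float = 6.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"degenerate range [{self.low}, {self.high}]")
        if self.sigma_cells < 0:
            raise ValueError("sigma_cells must be >= 0")


#: The nine covariates with field-realistic ranges (WorldClim/ISRIC/SRTM-like
#: units): vapour pressure kPa, temperature deg C, solar radiation
#: kJ m-2 day-1, precipitation mm, soil water %, soil depth cm, elevation m,
#: slope deg; soil_class is integer-coded.
DEFAULT_COVARIATES: dict[str, LayerSpec] = {
    "vapor_pressure": LayerSpec(0.1, 3.2),
    "temperature": LayerSpec(-2.0, 35.0),
    "solar_radiation": LayerSpec(8000.0, 28000.0),
    "precipitation": LayerSpec(100.0, 2600.0),
    "soil_water": LayerSpec(5.0, 45.0),
    "soil_class": LayerSpec(1, 6, 10.0),
    "soil_depth": LayerSpec(0.0, 200.0),
    "elevation": LayerSpec(0.0, 4500.0),
    "slope": LayerSpec(0.0, 30.0),
}

_DEFAULT_LANDUSE_PROBS = {8: 0.18, 9: 0.15, 6: 0.05, 7: 0.12, 10: 0.18, 12: 0.14, 2: 0.12, 16: 0.06}


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study region.

    The default grid spans 22 degrees of latitude at the analysis resolution
    of 0.05 degrees, so latitude-dependent cell areas are exercised; the
    default 1923 presence records are drawn with replacement so that gridding
    has duplicates to collapse.
    """

    grid_shape: tuple[int, int] = (440, 240)
    resolution_deg: float = 0.05
    origin: tuple[float, float] = (-6.0, 32.0)
    n_presence: int = 1923
    covariate_specs: dict[str, LayerSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    true_weights: dict[str, float] = field(
        default_factory=lambda: {"temperature": 2.5, "precipitation": 1.0}
    )
    true_quadratic: dict[str, float] = field(default_factory=dict)
    landuse_class_probs: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LANDUSE_PROBS)
    )
    border_fraction: float = 0.04
    temperature_gradient_weight: float = 0.65
    envelope: EnvelopeRule = field(default_factory=EnvelopeRule)
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape must be positive")
        if self.resolution_deg <= 0:
            raise ValueError("resolution_deg must be > 0")
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        if not 0 <= self.border_fraction < 0.5:
            raise ValueError("border_fraction must be in [0, 0.5)")
        for name, spec in self.covariate_specs.items():
            if not isinstance(spec, LayerSpec):
                raise TypeError(f"covariate_specs[{name!r}] must be a LayerSpec")
        env = self.envelope
        t = self.covariate_specs["temperature"]
        if not (t.low < env.temp_low or t.high > env.temp_high):
            raise ValueError(
                f"temperature range [{t.low}, {t.high}] lies inside the envelope "
                f"({env.temp_low}, {env.temp_high}); pseudo-absence sampling infeasible"
            )
        p = self.covariate_specs["precipitation"]
        if not (p.low < env.precip_low or p.high > env.precip_high):
            raise ValueError(
                f"precipitation range [{p.low}, {p.high}] lies inside the envelope "
                f"({env.precip_low}, {env.precip_high}); pseudo-absence sampling infeasible"
            )

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_shape, self.resolution_deg, self.origin)


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Spatially autocorrelated field, rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def _border_mask(shape, fraction) -> np.ndarray:
    """True where cells carry data (the interior); the border ring is 'ocean'."""
    rows, cols = shape
    br = int(round(rows * fraction))
    bc = int(round(cols * fraction))
    mask = np.zeros(shape, dtype=bool)
    mask[br: rows - br if br else rows, bc: cols - bc if bc else cols] = True
    return mask


def generate_env_stack(config: SyntheticConfig) -> EnvStack:
    """Generate the nine-covariate environmental stack.

    Continuous layers are Gaussian-smoothed white noise affinely rescaled to
    each covariate's range; temperature additionally carries a monotone
    north–south gradient; soil class is a clumped integer layer; a border
    ring of NoData plays the ocean. Raises if fewer than 1% of valid cells
    satisfy the pseudo-absence envelope.
    """
    grid = config.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    valid = _border_mask(config.grid_shape, config.border_fraction)
    layers: dict[str, Raster] = {}
    for name, spec in config.covariate_specs.items():
        f = _smooth_field(config.grid_shape, spec.sigma_cells, rng)
        if name == "temperature":
            # colder at the grid's northern rows, warmer toward the south
            grad = np.linspace(0.0, 1.0, config.grid_shape[0])[:, None]
            w = config.temperature_gradient_weight
            f = (1 - w) * f + w * np.broadcast_to(grad, config.grid_shape)
            f = (f - f.min()) / (f.max() - f.min())
        if name == "soil_class":
            n_classes = int(spec.high - spec.low) + 1
            vals = (np.ceil(rankdata(f, method="ordinal").reshape(config.grid_shape)
                            / f.size * n_classes) + spec.low - 1).astype(int)
            vals = np.where(valid, vals, -9999)
            layers[name] = Raster(vals, grid, name=name, nodata=-9999, categorical=True)
        else:
            vals = spec.low + f * (spec.high - spec.low)
            vals = np.where(valid, vals, np.nan)
            layers[name] = Raster(vals, grid, name=name)
    stack = EnvStack(layers)
    from .occurrences import envelope_mask

    frac = envelope_mask(stack, config.envelope).values[valid].mean()
    if frac < 0.01:
        raise RuntimeError(
            f"only {frac:.2%} of valid cells satisfy the pseudo-absence envelope; "
            "widen the temperature/precipitation ranges"
        )
    return stack


def true_suitability(
    stack: EnvStack,
    weights: dict[str, float],
    quadratic: dict[str, float] | None = None,
) -> Raster:
    """Known ground-truth suitability: inverse-logit of a weighted sum.

    Continuous covariates are standardized over valid cells before weighting;
    optional per-covariate quadratic terms act on the standardized scale.
    NoData propagates.
    """
    valid = stack.valid
    eta = np.zeros(stack.grid.shape)
    for name, w in weights.items():
        z = _standardized(stack[name], valid)
        eta += w * z
    for name, q in (quadratic or {}).items():
        z = _standardized(stack[name], valid)
        eta += q * z**2
    prob = expit(eta)
    prob = np.where(valid, prob, np.nan)
    return Raster(prob, stack.grid, name="true_suitability")


def _standardized(layer: Raster, valid: np.ndarray) -> np.ndarray:
    vals = np.asarray(layer.values, dtype=float)
    v = vals[valid]
    sd = v.std()
    z = (vals - v.mean()) / (sd if sd > 0 else 1.0)
    return np.where(valid, z, 0.0)


def sample_occurrences(suitability: Raster, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` occurrence records proportional to suitability.

    Cells are drawn *with replacement* (duplicate records, as in a raw
    occurrence download) and each record is jittered uniformly within its
    cell. Returns columns ``lon, lat, record_id``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.asarray(suitability.values, dtype=float).copy()
    p[~suitability.valid] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    flat = rng.choice(p.size, size=n, replace=True, p=p.ravel() / total)
    grid = suitability.grid
    row, col = flat // grid.cols, flat % grid.cols
    u, v = rng.random(n), rng.random(n)
    lon = grid.origin[0] + (col + u) * grid.resolution_deg
    lat = grid.origin[1] - (row + v) * grid.resolution_deg
    return pd.DataFrame({"lon": lon, "lat": lat, "record_id": np.arange(n)})


def generate_landuse(config: SyntheticConfig) -> Raster:
    """Spatially clumped integer-coded land-cover map.

    Class fractions follow ``landuse_class_probs`` (must sum to 1): a single
    smoothed random field is rank-transformed to uniform and sliced at the
    cumulative class probabilities, which makes classes contiguous level
    bands (clumped, not salt-and-pepper) with near-exact requested fractions.
    """
    probs = config.landuse_class_probs
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"land-use class probabilities sum to {total}, not 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    f = _smooth_field(config.grid_shape, 8.0, rng)
    u = rankdata(f, method="ordinal").reshape(config.grid_shape) / f.size
    codes = np.fromiter(probs.keys(), dtype=int)
    cum = np.cumsum(np.fromiter(probs.values(), dtype=float))
    cls = codes[np.minimum(np.searchsorted(cum, u), len(codes) - 1)]
    valid = _border_mask(config.grid_shape, config.border_fraction)
    vals = np.where(valid, cls, -9999)
    return Raster(vals, config.grid, name="landuse", nodata=-9999, categorical=True)


def generate_zones(config: SyntheticConfig, n_zones: int = 3) -> tuple[Raster, dict[int, str]]:
    """Longitudinal-block zone raster (stand-in for continents/countries)."""
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    rows, cols = config.grid_shape
    zone = (np.arange(cols) * n_zones // cols)[None, :] + 1
    vals = np.broadcast_to(zone, (rows, cols)).copy()
    valid = _border_mask(config.grid_shape, config.border_fraction)
    vals = np.where(valid, vals, -9999)
    names = {k + 1: f"zone_{k + 1}" for k in range(n_zones)}
    return Raster(vals, config.grid, name="zones", nodata=-9999, categorical=True), names
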