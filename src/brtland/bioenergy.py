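"""Biodiesel volume and greenhouse-gas abatement scenario arithmetic.

Converts a marginal-land area into a range of annual biodiesel volumes and
the corresponding CO2-equivalent abatement, expressed against an annual
emissions-reduction goal (28 GtCO2e for the 1.5 degC pathway):

    volume [L]     = area [ha] * utilization * yield [L/ha]
    abatement [kg] = volume [L] * abatement factor [kg CO2e / L]
    goal share [%] = abatement / goal * 100

The default yield and per-litre abatement bounds are *back-calculated* from
published global scenario figures for Pistacia chinensis biodiesel (1311.85
Mha of marginal land; 625.90-1112.19 billion litres at 50% utilization;
0.73 and 2.92 kg CO2e abated per litre), not taken from primary agronomic
sources; supply your own coefficients for any serious use.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScenarioParams",
    "ScenarioResult",
    "biodiesel_scenario",
    "implied_yield",
    "DEFAULT_TOTAL_AREA_MHA",
    "DEFAULT_GOAL_GT",
]

#: Published global marginal-land total for P. chinensis, Mha.
DEFAULT_TOTAL_AREA_MHA = 1311.85
#: Annual emissions-reduction goal, Gt CO2e.
DEFAULT_GOAL_GT = 28.0

#: Derived default yield bounds, litres biodiesel per hectare per year.
DEFAULT_YIELD_LOW = 625.90e9 / (DEFAULT_TOTAL_AREA_MHA * 1e6 * 0.5)
DEFAULT_YIELD_HIGH = 1112.19e9 / (DEFAULT_TOTAL_AREA_MHA * 1e6 * 0.5)
#: Derived default per-litre abatement bounds, kg CO2e per litre.
DEFAULT_ABATEMENT_LOW = 0.73
DEFAULT_ABATEMENT_HIGH = 2.92


@dataclass(frozen=True)
class ScenarioParams:
    """Inputs of one utilization scenario.

    total_area: marginal land, million hectares.
    utilization_fraction: share of that land actually cultivated, (0, 1].
    yield_low/high: biodiesel yield bounds, litres per hectare per year.
    abatement_low/high: GHG abatement per litre, kg CO2e.
    goal: annual emissions-reduction goal, Gt CO2e.
    """

    total_area: float = DEFAULT_TOTAL_AREA_MHA
    utilization_fraction: float = 0.3
    yield_low: float = DEFAULT_YIELD_LOW
    yield_high: float = DEFAULT_YIELD_HIGH
    abatement_low: float = DEFAULT_ABATEMENT_LOW
    abatement_high: float = DEFAULT_ABATEMENT_HIGH
    goal: float = DEFAULT_GOAL_GT

    def __post_init__(self) -> None:
        if self.total_area <= 0:
            raise ValueError("total_area must be positive")
        if not 0 < self.utilization_fraction <= 1:
            raise ValueError("utilization_fraction must be in (0, 1]")
        if not 0 <= self.yield_low <= self.yield_high:
            raise ValueError("need 0 <= yield_low <= yield_high")
        if not 0 <= self.abatement_low <= self.abatement_high:
            raise ValueError("need 0 <= abatement_low <= abatement_high")
        if self.goal <= 0:
            raise ValueError("goal must be positive")


@dataclass(frozen=True)
class ScenarioResult:
    """Scenario outputs; unrounded — round only at report time."""

    volume_low: float   # billion litres / yr
    volume_high: float
    abatement_low: float  # Gt CO2e / yr
    abatement_high: float
    goal_share_low: float  # percent of the goal
    goal_share_high: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report-format values (round-half-even, two decimals)."""
        return {k: round(v, ndigits) for k, v in self.__dict__.items()}


def biodiesel_scenario(params: ScenarioParams) -> ScenarioResult:
    """Compute volume, abatement and goal-share ranges for one scenario.

    Bounds are cross-matched low*low / high*high so low <= high throughout.
    """
    ha = params.total_area * 1e6 * params.utilization_fraction
    vol_low_l = ha * params.yield_low
    vol_high_l = ha * params.yield_high
    abate_low_gt = vol_low_l * params.abatement_low / 1e12  # kg -> Gt
    abate_high_gt = vol_high_l * params.abatement_high / 1e12
    return ScenarioResult(
        volume_low=vol_low_l / 1e9,
        volume_high=vol_high_l / 1e9,
        abatement_low=abate_low_gt,
        abatement_high=abate_high_gt,
        goal_share_low=100.0 * abate_low_gt / params.goal,
        goal_share_high=100.0 * abate_high_gt / params.goal,
    )


def implied_yield(total_area_mha: float, utilization: float, volume_bl: float) -> float:
    """Back-calculate litres/ha from a reported volume (BL) and area basis."""
    if total_area_mha <= 0 or utilization <= 0:
        raise ValueError("area and utilization must be positive")
    if volume_bl < 0:
        raise ValueError("volume must be nonnegative")
    return volume_bl * 1e9 / (total_area_mha * 1e6 * utilization)
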