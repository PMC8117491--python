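"""Aggregation of media concentrations into weekly external doses.

Combines ingestion (local and market foods, tap water, incidental soil) and
inhalation pathways for a target subpopulation (default: pregnant women),
with self-consumption fractions that depend on the urban-unit size class of
the cell and lower/upper-bound market-food scenarios. The dermal pathway is
excluded from aggregation; the toxicokinetic stage keeps a dermal input slot
set to zero.

Units: ingestion doses mg/kg bw/d; inhaled air concentration ng/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureProfile",
    "SelfConsumptionScenario",
    "classify_urban_unit",
    "inhaled_concentration",
    "ingestion_dose",
    "inhalation_dose",
    "weekly_dose_table",
    "FOOD_GROUPS",
    "DEFAULT_SELF_CONSUMPTION",
]

FOOD_GROUPS = ("apple", "lettuce", "potato", "tomato")

NG_PER_MG = 1e6
UG_PER_MG = 1e3


@dataclass(frozen=True)
class ExposureProfile:
    """Exposure factors for one subpopulation. Defaults describe an adult
    pregnant woman (illustrative central values)."""

    name: str = "pregnant"
    body_weight: float = 67.0  # kg
    food_intake: dict = field(
        default_factory=lambda: {"apple": 0.060, "lettuce": 0.030,
                                 "potato": 0.100, "tomato": 0.060}
    )  # kg fw/d per food group
    water_intake: float = 1.5  # L/d
    soil_ingestion: float = 50.0  # mg/d
    inhalation_rate: float = 13.3  # m^3/d
    age_class: str = "adult"

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body weight must be > 0")
        if (self.water_intake < 0 or self.soil_ingestion < 0
                or self.inhalation_rate < 0 or any(v < 0 for v in self.food_intake.values())):
            raise ValueError("intake rates must be >= 0")


#: Self-consumption fraction of each food group by urban-unit class; rural
#: municipalities grow more of their own produce (illustrative defaults).
DEFAULT_SELF_CONSUMPTION = {1: 0.35, 2: 0.25, 3: 0.12, 4: 0.03}


@dataclass(frozen=True)
class SelfConsumptionScenario:
    """Fraction of each food group sourced from local gardens, per urban-unit
    size class (1: < 2000 inhabitants ... 4: > 100,000)."""

    urban_class: int
    fractions: dict = field(default_factory=dict)

    def fraction(self, food_group: str) -> float:
        f = self.fractions.get(food_group, DEFAULT_SELF_CONSUMPTION[self.urban_class])
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"self-consumption fraction {f} outside [0, 1]")
        return f


def classify_urban_unit(inhabitants: float) -> int:
    """Urban-unit size class from municipality population.

    Left-closed boundaries: class 1 below 2000; class 2 in [2000, 10,000);
    class 3 in [10,000, 100,000); class 4 at or above 100,000.
    """
    if inhabitants < 0:
        raise ValueError("inhabitants must be >= 0")
    if inhabitants < 2000:
        return 1
    if inhabitants < 10000:
        return 2
    if inhabitants < 100000:
        return 3
    return 4


def inhaled_concentration(c_gas, c_part):
    """Inhalation-relevant air concentration: sum of the gaseous and
    particulate forms (ng/m^3); vectorizes over arrays."""
    c_gas = np.asarray(c_gas, dtype=float)
    c_part = np.asarray(c_part, dtype=float)
    if np.any(c_gas < 0) or np.any(c_part < 0):
        raise ValueError("air concentrations must be >= 0")
    out = c_gas + c_part
    return float(out) if out.ndim == 0 else out


def inhalation_dose(c_inh, profile: ExposureProfile):
    """Inhaled dose (mg/kg bw/d) from air concentration in ng/m^3."""
    return np.asarray(c_inh, dtype=float) * profile.inhalation_rate / NG_PER_MG / profile.body_weight


def ingestion_dose(
    c_local: dict[str, float],
    c_market: dict[str, tuple[float, float]],
    c_water: float,
    c_soil: float,
    profile: ExposureProfile,
    scenario: SelfConsumptionScenario,
    market_scenario: str,
) -> float:
    """Weekly-support ingestion dose (mg/kg bw/d) for one cell and substance.

    dose = [ sum_f IR_f (sc_f C_local,f + (1 - sc_f) C_market,f)
             + IR_w C_water + IR_s 1e-6 C_soil ] / BW

    ``c_local`` in mg/kg fw per food group; ``c_market`` maps food group to an
    (LB, UB) pair in mg/kg fw, selected by ``market_scenario``; ``c_water`` in
    ug/L (converted to mg/L internally); ``c_soil`` in mg/kg.
    """
    ms = market_scenario.upper()
    if ms not in ("LB", "UB"):
        raise ValueError(f"market_scenario must be LB or UB, got {market_scenario!r}")
    total = 0.0
    for group, ir in profile.food_intake.items():
        if group not in c_local:
            raise KeyError(f"missing local concentration for food group {group!r}")
        if group not in c_market:
            raise KeyError(f"missing market concentration for food group {group!r}")
        sc = scenario.fraction(group)
        cm = c_market[group][0 if ms == "LB" else 1]
        total += ir * (sc * c_local[group] + (1.0 - sc) * cm)
    total += profile.water_intake * (c_water / UG_PER_MG)
    total += profile.soil_ingestion * 1e-6 * c_soil
    return total / profile.body_weight


def weekly_dose_table(
    region_shape: tuple[int, int],
    media: dict,
    urban_class_map: np.ndarray,
    profile: ExposureProfile,
    self_consumption: dict[int, float] | None = None,
    market_scenarios: tuple[str, ...] = ("LB", "UB"),
) -> dict[str, np.ndarray]:
    """Vectorized per-cell, per-week external doses for each market scenario.

    ``media`` keys (per substance handled by the caller):
      ``c_gas``/``c_part``: (n_weeks, n_cells) ng/m^3;
      ``c_soil``: (n_weeks, n_cells) mg/kg; ``c_water``: (n_cells,) ug/L;
      ``c_local``: food group -> (n_weeks, n_cells) mg/kg fw;
      ``c_market``: food group -> (LB, UB) scalars mg/kg fw.

    Returns ``{'ingestion_LB', 'ingestion_UB', 'inhalation', 'c_inh'}`` arrays
    of shape (n_weeks, n_cells) (ingestion only for requested scenarios).
    """
    sc_by_class = dict(DEFAULT_SELF_CONSUMPTION)
    if self_consumption:
        sc_by_class.update({int(k): float(v) for k, v in self_consumption.items()})
    classes = np.asarray(urban_class_map).ravel()
    n_cells = classes.size
    if n_cells != region_shape[0] * region_shape[1]:
        raise ValueError(
            f"urban class map size {n_cells} does not match grid {region_shape}"
        )
    sc_cell = np.array([sc_by_class[int(c)] for c in classes])

    c_gas = np.asarray(media["c_gas"], dtype=float)
    c_part = np.asarray(media["c_part"], dtype=float)
    n_weeks = c_gas.shape[0]
    if c_gas.shape[1] != n_cells:
        raise ValueError(f"media cube shape {c_gas.shape} does not match grid {region_shape}")
    c_inh = inhaled_concentration(c_gas, c_part)

    out: dict[str, np.ndarray] = {
        "c_inh": c_inh,
        "inhalation": inhalation_dose(c_inh, profile),
    }
    c_soil = np.asarray(media["c_soil"], dtype=float)
    c_water = np.asarray(media["c_water"], dtype=float).reshape(1, n_cells)
    for ms in market_scenarios:
        total = np.zeros((n_weeks, n_cells))
        for group, ir in profile.food_intake.items():
            c_local = np.asarray(media["c_local"][group], dtype=float)
            cm = media["c_market"][group][0 if ms.upper() == "LB" else 1]
            total += ir * (sc_cell[None, :] * c_local + (1.0 - sc_cell[None, :]) * cm)
        total += profile.water_intake * (c_water / UG_PER_MG)
        total += profile.soil_ingestion * 1e-6 * c_soil
        out[f"ingestion_{ms.upper()}"] = total / profile.body_weight
    return out
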