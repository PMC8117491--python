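"""Multimedia transfer: deposition and soil burden to local-food concentrations.

Mass-balance formulation with first-order kinetics throughout. The soil
compartment follows a linear ODE with closed-form integration; each crop is a
small linear compartment system (<= 5 compartments: root, stem, leaf, fruit,
tuber as relevant) with time-varying biomasses, Beer-Lambert interception of
atmospheric deposits on the canopy, root uptake from soil, inter-compartment
transfer coefficients, and first-order loss. Concentrations are evaluated in
the edible compartment at harvest; lettuce, harvested year-round, is weighted
over weeks by the leaf area index (LAI).

A fast alternative ("BCF mode") estimates edible-organ concentrations from
bioconcentration factors applied to cultivation-averaged gas-phase air and
soil concentrations.

All default crop parameters are illustrative magnitudes, not measured values;
the configuration table is the interface for realism.

Units: soil mg/kg dw; deposition inputs mg/m^2/d; plant masses mg/m^2 ground;
biomasses kg fw/m^2 ground; harvest concentrations mg/kg fw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SoilCell",
    "CropParams",
    "CropState",
    "update_soil",
    "simulate_crop",
    "crop_propagators",
    "lettuce_weighted_concentration",
    "bcf_foliage_concentration",
    "DEFAULT_CROPS",
    "EDIBLE",
]

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class SoilCell:
    """Topsoil mixing layer treated as a well-mixed reservoir."""

    concentration: float = 0.0  # mg/kg dw
    mixing_depth: float = 0.20  # m
    bulk_density: float = 1300.0  # kg/m^3
    k_s: float = 0.023  # 1/d (~30 d dissipation half-life)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("soil concentration must be >= 0")
        if self.mixing_depth <= 0 or self.bulk_density <= 0:
            raise ValueError("mixing depth and bulk density must be > 0")
        if self.k_s < 0:
            raise ValueError("dissipation rate must be >= 0")


def update_soil(cell: SoilCell, deposition_rate: float, soil_application_rate: float,
                dt: float) -> SoilCell:
    """Advance the soil concentration over ``dt`` days under constant inputs.

    Solves dC/dt = (D + A)/(rho d) - k C exactly:
    C(dt) = C0 e^{-k dt} + R/k (1 - e^{-k dt}) with R the input term, and the
    k -> 0 limit C0 + R dt. Inputs are areal rates in mg/m^2/d.
    """
    if deposition_rate < 0 or soil_application_rate < 0:
        raise ValueError("input rates must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    r = (deposition_rate + soil_application_rate) / (cell.bulk_density * cell.mixing_depth)
    k = cell.k_s
    if k > 0:
        c = cell.concentration * np.exp(-k * dt) + (r / k) * (1.0 - np.exp(-k * dt))
    else:
        c = cell.concentration + r * dt
    return replace(cell, concentration=float(c))


# ---------------------------------------------------------------------------
# Crop compartment systems
# ---------------------------------------------------------------------------

EDIBLE = {"apple": "fruit", "tomato": "fruit", "lettuce": "leaf", "potato": "tuber"}


@dataclass
class CropParams:
    """Compartmental plant model for one crop.

    ``transfers`` lists first-order coefficients (1/d) from one compartment to
    another (xylem/phloem-like flows); ``k_loss`` is the per-compartment
    first-order loss (degradation + growth dilution + wash-off, 1/d);
    ``k_int`` scales Beer-Lambert canopy interception 1 - exp(-k_int * LAI);
    ``k_root`` (kg soil / kg root fw / d) scales root uptake from soil.
    ``biomass``/``lai`` are callables of the week index over the season.
    """

    crop: str
    compartments: tuple[str, ...]
    transfers: dict[tuple[str, str], float]
    k_loss: dict[str, float]
    k_int: float
    k_root: float
    biomass: dict[str, object]  # compartment -> callable(week)-> kg fw/m^2
    lai: object  # callable(week) -> m^2/m^2
    season: tuple[int, int] = (14, 40)  # growing-season weeks (inclusive)
    intercepting: tuple[str, ...] = ("leaf",)

    @property
    def edible(self) -> str:
        return EDIBLE[self.crop]


@dataclass
class CropState:
    """Compartment masses (mg/m^2 ground) during a growing season."""

    params: CropParams
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.masses is None:
            self.masses = np.zeros(len(self.params.compartments))
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses < 0):
            raise ValueError("compartment masses must be >= 0")


def _system_matrix(p: CropParams, week: int) -> np.ndarray:
    comp = p.compartments
    n = len(comp)
    K = np.zeros((n, n))
    for (src, dst), k in p.transfers.items():
        i, j = comp.index(src), comp.index(dst)
        K[j, i] += k
        K[i, i] -= k
    for c, k in p.k_loss.items():
        i = comp.index(c)
        K[i, i] -= k
    return K


def _source_vector(p: CropParams, week: int, deposition: float, c_soil: float) -> np.ndarray:
    """Inputs in mg/m^2/d: canopy interception of deposits + root uptake."""
    comp = p.compartments
    s = np.zeros(len(comp))
    lai = max(float(p.lai(week)), 0.0)
    intercepted = deposition * (1.0 - np.exp(-p.k_int * lai))
    targets = [c for c in p.intercepting if c in comp]
    for c in targets:
        s[comp.index(c)] += intercepted / len(targets)
    if "root" in comp:
        b_root = max(float(p.biomass["root"](week)), 0.0)
        s[comp.index("root")] += p.k_root * c_soil * b_root
    return s


def crop_propagators(p: CropParams, weeks: np.ndarray):
    """Weekly propagators for the linear system dM/dt = K M + S(t).

    Returns ``(Phi, Psi)`` lists where M_{k+1} = Phi_k M_k + Psi_k @ [dep_k,
    soil_k]; computed once per crop and reused across grid cells (the system
    matrix depends on the week, not the cell)."""
    n = len(p.compartments)
    phis, psis = [], []
    dt = DAYS_PER_WEEK
    for w in weeks:
        K = _system_matrix(p, int(w))
        s_dep = _source_vector(p, int(w), 1.0, 0.0)
        s_soil = _source_vector(p, int(w), 0.0, 1.0)
        B = np.column_stack([s_dep, s_soil])
        aug = np.zeros((n + 2, n + 2))
        aug[:n, :n] = K * dt
        aug[:n, n:] = B * dt
        e = expm(aug)
        phis.append(e[:n, :n])
        psis.append(e[:n, n:])
    return phis, psis


def simulate_crop(
    state: CropState,
    deposition_series: np.ndarray,
    soil_series: np.ndarray,
    season: tuple[int, int] | None = None,
) -> float:
    """Integrate the crop system over the season and return the edible-organ
    concentration at harvest (mg/kg fw).

    ``deposition_series`` (mg/m^2/d) and ``soil_series`` (mg/kg) are weekly
    values indexed by absolute week; the system is integrated with exact
    piecewise-constant linear-ODE steps from season start to harvest (season
    end). Raises if the edible biomass at harvest is zero.
    """
    p = state.params
    w0, w1 = season or p.season
    weeks = np.arange(w0, w1 + 1)
    if w1 >= len(deposition_series) or w1 >= len(soil_series):
        raise ValueError("season extends past the supplied weekly series")
    phis, psis = crop_propagators(p, weeks)
    m = state.masses.copy()
    for k, w in enumerate(weeks):
        u = np.array([max(float(deposition_series[w]), 0.0),
                      max(float(soil_series[w]), 0.0)])
        m = phis[k] @ m + psis[k] @ u
    edible = p.edible
    b = float(p.biomass[edible](int(w1)))
    if b <= 0:
        raise ValueError(f"{p.crop}: zero edible biomass at harvest week {w1}")
    return float(m[p.compartments.index(edible)] / b)


def simulate_crop_weekly(
    state: CropState,
    deposition_series: np.ndarray,
    soil_series: np.ndarray,
    season: tuple[int, int] | None = None,
) -> np.ndarray:
    """As :func:`simulate_crop` but returning the edible concentration at the
    end of every season week (used for LAI-weighted year-round harvests)."""
    p = state.params
    w0, w1 = season or p.season
    weeks = np.arange(w0, w1 + 1)
    phis, psis = crop_propagators(p, weeks)
    m = state.masses.copy()
    ei = p.compartments.index(p.edible)
    out = np.zeros(len(weeks))
    for k, w in enumerate(weeks):
        u = np.array([max(float(deposition_series[w]), 0.0),
                      max(float(soil_series[w]), 0.0)])
        m = phis[k] @ m + psis[k] @ u
        b = float(p.biomass[p.edible](int(w)))
        out[k] = m[ei] / b if b > 0 else 0.0
    return out


def lettuce_weighted_concentration(weekly_concs: np.ndarray, lai_series: np.ndarray) -> float:
    """Harvest-probability weighting of weekly concentrations by the LAI:
    w_k = LAI_k / sum LAI; returns sum w_k C_k."""
    c = np.asarray(weekly_concs, dtype=float)
    lai = np.asarray(lai_series, dtype=float)
    if c.shape != lai.shape:
        raise ValueError("weekly concentrations and LAI series must align")
    tot = lai.sum()
    if tot <= 0:
        raise ValueError("all-zero LAI: no harvest possible")
    return float((lai / tot) @ c)


def bcf_foliage_concentration(
    c_gas_timeavg: float,
    c_soil_timeavg: float,
    crop_category: str,
    bcf_table: dict[str, tuple[float, float]],
) -> float:
    """BCF route: C_plant = BCF_air * C_gas_avg + BCF_soil * C_soil_avg.

    ``bcf_table`` maps crop category -> (BCF_air in (mg/kg)/(ng/m^3),
    BCF_soil in (mg/kg)/(mg/kg)); the inputs are cultivation-period means.
    """
    if crop_category not in bcf_table:
        raise KeyError(f"no BCF entry for crop category {crop_category!r}")
    if c_gas_timeavg < 0 or c_soil_timeavg < 0:
        raise ValueError("time-averaged concentrations must be >= 0")
    bcf_air, bcf_soil = bcf_table[crop_category]
    return float(bcf_air * c_gas_timeavg + bcf_soil * c_soil_timeavg)


# ---------------------------------------------------------------------------
# Illustrative default crop parameterization
# ---------------------------------------------------------------------------

def _logistic_biomass(b_max: float, w_mid: float, rate: float = 0.35):
    return lambda w: b_max / (1.0 + np.exp(-rate * (w - w_mid)))


def _season_lai(lai_max: float, w0: int, w1: int):
    def f(w):
        if w < w0 or w > w1:
            return 0.0
        return lai_max * np.sin(np.pi * (w - w0) / max(w1 - w0, 1)) ** 2
    return f


def _make_default_crops() -> dict[str, CropParams]:
    crops: dict[str, CropParams] = {}
    crops["apple"] = CropParams(
        crop="apple",
        compartments=("root", "stem", "leaf", "fruit"),
        transfers={("root", "stem"): 0.05, ("stem", "leaf"): 0.04,
                   ("stem", "fruit"): 0.03, ("leaf", "fruit"): 0.02},
        k_loss={"root": 0.02, "stem": 0.02, "leaf": 0.10, "fruit": 0.03},
        k_int=0.5,
        k_root=0.002,
        biomass={"root": _logistic_biomass(1.5, 10), "stem": _logistic_biomass(3.0, 10),
                 "leaf": _logistic_biomass(0.8, 20), "fruit": _logistic_biomass(2.0, 30)},
        lai=_season_lai(3.0, 14, 40),
        season=(14, 40),
        intercepting=("leaf", "fruit"),
    )
    crops["tomato"] = CropParams(
        crop="tomato",
        compartments=("root", "stem", "leaf", "fruit"),
        transfers={("root", "stem"): 0.06, ("stem", "leaf"): 0.05,
                   ("stem", "fruit"): 0.04, ("leaf", "fruit"): 0.03},
        k_loss={"root": 0.03, "stem": 0.03, "leaf": 0.12, "fruit": 0.04},
        k_int=0.6,
        k_root=0.003,
        biomass={"root": _logistic_biomass(0.3, 22), "stem": _logistic_biomass(0.6, 24),
                 "leaf": _logistic_biomass(0.5, 24), "fruit": _logistic_biomass(1.5, 30)},
        lai=_season_lai(2.5, 20, 38),
        season=(20, 38),
        intercepting=("leaf", "fruit"),
    )
    crops["lettuce"] = CropParams(
        crop="lettuce",
        compartments=("root", "leaf"),
        transfers={("root", "leaf"): 0.08},
        k_loss={"root": 0.03, "leaf": 0.10},
        k_int=0.8,
        k_root=0.004,
        biomass={"root": lambda w: 0.05, "leaf": lambda w: 0.4},
        lai=_season_lai(2.0, 0, 51),
        season=(0, 51),  # harvested year-round; LAI-weighted
        intercepting=("leaf",),
    )
    crops["potato"] = CropParams(
        crop="potato",
        compartments=("root", "leaf", "tuber"),
        transfers={("root", "tuber"): 0.04, ("leaf", "tuber"): 0.02},
        k_loss={"root": 0.03, "leaf": 0.12, "tuber": 0.02},
        k_int=0.6,
        k_root=0.004,
        biomass={"root": _logistic_biomass(0.2, 20), "leaf": _logistic_biomass(0.4, 22),
                 "tuber": _logistic_biomass(3.0, 30)},
        lai=_season_lai(3.5, 16, 38),
        season=(16, 38),
        intercepting=("leaf",),
    )
    return crops


#: Illustrative parameter tables (magnitudes only, not measured values).
DEFAULT_CROPS = _make_default_crops()
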