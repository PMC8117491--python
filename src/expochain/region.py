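"""Synthetic study region: reference grid, parcels, applications, weather, monitoring.

The downstream chain (dispersion -> geostatistics -> multimedia -> dose -> PBPK)
is exercised on a synthetic agricultural region with the statistical structure
of a northern-France arable landscape: a regular reference grid (default cell
4 km^2), rectangular crop parcels carrying annual applied pesticide masses,
3-hourly surface meteorology, sparse monitoring networks with LOD/LOQ
censoring, and a population layer organised in urban units.

All generators are deterministic for a fixed ``(config, seed)`` pair: every
operation draws from a single ``numpy.random.Generator`` seeded at call time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

__all__ = [
    "StudyRegion",
    "Parcel",
    "PopulationLayer",
    "MetParams",
    "generate_region",
    "generate_applications",
    "generate_met",
    "sample_monitoring",
    "pasquill_class",
    "STATUS_QUANTIFIED",
    "STATUS_BELOW_LOQ",
    "STATUS_NON_DETECT",
]

CROPS = ("apple", "lettuce", "potato", "tomato", "cereal")

STATUS_QUANTIFIED = "quantified"
STATUS_BELOW_LOQ = "detected_below_LOQ"
STATUS_NON_DETECT = "non_detect"


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its preconditions."""


@dataclass(frozen=True)
class StudyRegion:
    """Regular row-major grid; cell (i, j) covers the half-open square
    ``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)``.

    Cell-centre coordinates are the support for all field evaluations.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 2000.0
    n_rows: int = 50
    n_cols: int = 50
    crs_label: str = "local metric grid"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates in row-major order."""
        x0, y0 = self.origin
        s = self.cell_size
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        xs = x0 + (jj.ravel() + 0.5) * s
        ys = y0 + (ii.ravel() + 0.5) * s
        return np.column_stack([xs, ys])

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the half-open cell containing (x, y); raises outside."""
        x0, y0 = self.origin
        j = int(np.floor((x - x0) / self.cell_size))
        i = int(np.floor((y - y0) / self.cell_size))
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside region bounds {self.bounds}")
        return i, j

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return (x0 <= x < x1) and (y0 <= y < y1)


@dataclass
class Parcel:
    """Agricultural parcel with a crop and annual applied masses (kg/yr)."""

    id: str
    polygon: Polygon
    crop: str
    annual_mass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ConfigurationError(f"parcel {self.id}: degenerate polygon")
        if self.crop not in CROPS:
            raise ConfigurationError(f"parcel {self.id}: unknown crop {self.crop!r}")
        for s, m in self.annual_mass.items():
            if m < 0:
                raise ConfigurationError(f"parcel {self.id}: negative mass for {s}")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass
class PopulationLayer:
    """Per-cell population counts and the size (inhabitants) of the urban unit
    (municipality) each cell belongs to."""

    population: np.ndarray  # (n_rows, n_cols) counts
    urban_unit_size: np.ndarray  # (n_rows, n_cols) municipality inhabitants

    def __post_init__(self) -> None:
        if np.any(self.population < 0) or np.any(self.urban_unit_size < 0):
            raise ConfigurationError("population counts must be >= 0")


# ---------------------------------------------------------------------------
# Region / parcels / population
# ---------------------------------------------------------------------------

def generate_region(config: dict, seed: int):
    """Build the study region, its parcels and the population layer.

    ``config`` keys (with defaults): ``n_rows``, ``n_cols``, ``cell_size``,
    ``origin``, ``n_parcels``, ``min_side``/``max_side`` (parcel side, m),
    ``crop_mix`` (crop -> probability), ``mean_annual_mass_kg`` (substance ->
    mean of the lognormal parcel mass distribution), ``n_municipalities``,
    ``mean_municipality_pop``.

    Returns ``(region, parcels, population_layer)``. Deterministic for fixed
    ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    region = StudyRegion(
        origin=tuple(config.get("origin", (0.0, 0.0))),
        cell_size=float(config.get("cell_size", 2000.0)),
        n_rows=int(config.get("n_rows", 50)),
        n_cols=int(config.get("n_cols", 50)),
        crs_label=str(config.get("crs_label", "local metric grid")),
    )
    x0, y0, x1, y1 = region.bounds

    n_parcels = int(config.get("n_parcels", 200))
    if n_parcels < 0:
        raise ConfigurationError("n_parcels must be >= 0")
    min_side = float(config.get("min_side", 200.0))
    max_side = float(config.get("max_side", 800.0))
    crop_mix = dict(config.get("crop_mix", {c: 1.0 / len(CROPS) for c in CROPS}))
    crops = sorted(crop_mix)
    probs = np.array([crop_mix[c] for c in crops], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ConfigurationError("crop_mix probabilities must be >= 0 and sum > 0")
    probs = probs / probs.sum()
    mass_means = dict(config.get("mean_annual_mass_kg", {}))

    parcels: list[Parcel] = []
    for k in range(n_parcels):
        w = rng.uniform(min_side, max_side)
        h = rng.uniform(min_side, max_side)
        cx = rng.uniform(x0 + w / 2, x1 - w / 2)
        cy = rng.uniform(y0 + h / 2, y1 - h / 2)
        crop = crops[rng.choice(len(crops), p=probs)]
        masses = {
            s: float(rng.lognormal(mean=np.log(max(mu, 1e-300)), sigma=0.5)) if mu > 0 else 0.0
            for s, mu in sorted(mass_means.items())
        }
        parcels.append(
            Parcel(
                id=f"P{k:04d}",
                polygon=box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                crop=crop,
                annual_mass=masses,
            )
        )

    pop = _generate_population(region, config, rng)
    return region, parcels, pop


def _generate_population(region: StudyRegion, config: dict, rng: np.random.Generator) -> PopulationLayer:
    """Voronoi-style municipalities around random seeds; municipality totals
    lognormal, spread over member cells with a density gradient to the seat."""
    n_mun = max(1, int(config.get("n_municipalities", 12)))
    mean_pop = float(config.get("mean_municipality_pop", 5000.0))
    x0, y0, x1, y1 = region.bounds
    seats = np.column_stack(
        [rng.uniform(x0, x1, size=n_mun), rng.uniform(y0, y1, size=n_mun)]
    )
    totals = rng.lognormal(mean=np.log(mean_pop), sigma=1.2, size=n_mun)
    centers = region.cell_centers()
    d2 = ((centers[:, None, :] - seats[None, :, :]) ** 2).sum(axis=2)
    member = np.argmin(d2, axis=1)  # municipality of each cell

    population = np.zeros(region.n_cells)
    uu_size = np.zeros(region.n_cells)
    for m in range(n_mun):
        mask = member == m
        if not mask.any():
            continue
        # density decays with distance from the municipality seat
        w = np.exp(-np.sqrt(d2[mask, m]) / (3.0 * region.cell_size))
        population[mask] = totals[m] * w / w.sum()
        uu_size[mask] = totals[m]
    return PopulationLayer(
        population=population.reshape(region.shape),
        urban_unit_size=uu_size.reshape(region.shape),
    )


# ---------------------------------------------------------------------------
# Application schedule
# ---------------------------------------------------------------------------

def generate_applications(
    parcels: list[Parcel],
    substances: list[str],
    calendar: dict,
    seed: int,
) -> pd.DataFrame:
    """Disaggregate each parcel's annual mass into tri-hourly application events.

    ``calendar`` maps each crop to a spreading window ``(first_step, last_step)``
    in 3-h step indices (inclusive) and carries ``events_per_parcel`` (int).
    Allocation rule: for each (parcel, substance) with positive mass, draw
    ``events_per_parcel`` distinct slots uniformly from the crop window and
    split the annual mass equally among them, so the schedule re-aggregates to
    the annual totals exactly.

    Returns a DataFrame with columns ``parcel_id, substance, timestep, mass_kg``.
    """
    rng = np.random.default_rng(seed)
    n_events = int(calendar.get("events_per_parcel", 2))
    windows = calendar.get("windows", {})
    rows = []
    for parcel in parcels:
        win = windows.get(parcel.crop)
        for substance in substances:
            mass = float(parcel.annual_mass.get(substance, 0.0))
            if mass == 0.0:
                continue
            if win is None:
                raise ConfigurationError(
                    f"no spreading window for crop {parcel.crop!r} "
                    f"but parcel {parcel.id} has positive mass"
                )
            lo, hi = int(win[0]), int(win[1])
            slots = np.arange(lo, hi + 1)
            if slots.size == 0:
                raise ConfigurationError(
                    f"empty spreading window for crop {parcel.crop!r}"
                )
            k = min(n_events, slots.size)
            chosen = np.sort(rng.choice(slots, size=k, replace=False))
            for t in chosen:
                rows.append((parcel.id, substance, int(t), mass / k))
    return pd.DataFrame(rows, columns=["parcel_id", "substance", "timestep", "mass_kg"])


# ---------------------------------------------------------------------------
# Meteorology
# ---------------------------------------------------------------------------

@dataclass
class MetParams:
    """Climate parameters for the 3-hourly weather generator.

    Wind speeds are Weibull distributed (shape/scale typical of NW-European
    surface stations) and floored at ``min_wind`` m/s; directions are von
    Mises around the prevailing direction; temperature follows an annual
    sinusoid plus noise; precipitation is a wet/dry Bernoulli with exponential
    amounts; cloudiness in octas.
    """

    prevailing_dir: float = 225.0  # degrees, direction wind blows FROM
    dir_kappa: float = 1.5
    weibull_shape: float = 2.0
    weibull_scale: float = 4.5  # m/s
    min_wind: float = 0.5  # calm floor; Gaussian plume undefined at u = 0
    temp_mean: float = 11.0  # degC
    temp_amplitude: float = 8.0
    temp_sigma: float = 2.5
    p_wet: float = 0.30
    mean_rain: float = 1.2  # mm per wet 3-h step
    mean_cloudiness: float = 5.0  # octas


# Pasquill stability assignment keyed on (wind speed, daytime flag, cloudiness).
# Daytime insolation is taken as moderate under <= 4 octas, slight otherwise;
# night classes split on >= 5 octas overcast.
def pasquill_class(wind_speed: float, daytime: bool, cloudiness: float) -> str:
    u = float(wind_speed)
    if daytime:
        if cloudiness <= 4:  # moderate insolation
            if u < 2:
                return "A"
            if u < 3:
                return "B"
            if u < 5:
                return "B"
            if u < 6:
                return "C"
            return "D"
        else:  # slight insolation
            if u < 2:
                return "B"
            if u < 5:
                return "C"
            return "D"
    else:
        if cloudiness >= 5:  # overcast night
            return "E" if u < 3 else "D"
        if u < 3:
            return "F"
        if u < 5:
            return "E"
        return "D"


def generate_met(n_steps: int, climate_params: MetParams | dict | None, seed: int) -> pd.DataFrame:
    """Generate a 3-hourly meteorological series of ``n_steps`` records.

    Returns a DataFrame with columns ``timestep, wind_speed, wind_dir,
    temperature, precipitation, humidity, cloudiness, stability_class``.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    if climate_params is None:
        p = MetParams()
    elif isinstance(climate_params, dict):
        p = MetParams(**climate_params)
    else:
        p = climate_params
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps)
    hours = (t * 3) % 24
    day_of_year = (t * 3 / 24.0) % 365.25

    wind = np.maximum(p.min_wind, p.weibull_scale * rng.weibull(p.weibull_shape, n_steps))
    wdir = np.degrees(rng.vonmises(np.radians(p.prevailing_dir), p.dir_kappa, n_steps)) % 360.0
    temp = (
        p.temp_mean
        - p.temp_amplitude * np.cos(2 * np.pi * (day_of_year - 15) / 365.25)
        + rng.normal(0, p.temp_sigma, n_steps)
    )
    wet = rng.random(n_steps) < p.p_wet
    rain = np.where(wet, rng.exponential(p.mean_rain, n_steps), 0.0)
    humidity = np.clip(rng.normal(75, 12, n_steps) + 10 * wet, 20, 100)
    cloud = np.clip(np.round(rng.normal(p.mean_cloudiness, 2.2, n_steps)), 0, 8)
    daytime = (hours >= 6) & (hours < 18)
    stability = [
        pasquill_class(u, bool(d), c) for u, d, c in zip(wind, daytime, cloud)
    ]
    return pd.DataFrame(
        {
            "timestep": t,
            "wind_speed": wind,
            "wind_dir": wdir,
            "temperature": temp,
            "precipitation": rain,
            "humidity": humidity,
            "cloudiness": cloud,
            "stability_class": stability,
        }
    )


# ---------------------------------------------------------------------------
# Monitoring networks
# ---------------------------------------------------------------------------

def sample_monitoring(
    true_fields: dict[str, np.ndarray],
    stations: pd.DataFrame,
    error_model: dict,
    region: StudyRegion,
    seed: int,
) -> pd.DataFrame:
    """Draw censored measurements of gridded true fields at monitoring stations.

    ``true_fields`` maps substance -> (n_rows, n_cols) array; ``stations`` has
    columns ``station_id, x, y, substance, LOD, LOQ`` (one row per station x
    substance); ``error_model['sigma']`` is the multiplicative lognormal noise
    standard deviation on the log scale.

    Each noisy draw is compared to the station's LOD/LOQ: below LOD the sample
    is a non-detect, between LOD and LOQ it is detected-but-not-quantified;
    only quantified samples carry a numeric value.
    """
    rng = np.random.default_rng(seed)
    sigma = float(error_model.get("sigma", 0.0))
    outside = [
        str(r.station_id)
        for r in stations.itertuples()
        if not region.contains(float(r.x), float(r.y))
    ]
    if outside:
        raise ValueError(f"stations outside region: {sorted(set(outside))}")

    rows = []
    for r in stations.itertuples():
        lod, loq = float(r.LOD), float(r.LOQ)
        if not (loq >= lod > 0):
            raise ConfigurationError(
                f"station {r.station_id}: require LOQ >= LOD > 0, got LOD={lod}, LOQ={loq}"
            )
        i, j = region.cell_index(float(r.x), float(r.y))
        true = float(true_fields[r.substance][i, j])
        noisy = true * np.exp(rng.normal(0.0, sigma)) if sigma > 0 else true
        if noisy < lod:
            status, value = STATUS_NON_DETECT, np.nan
        elif noisy < loq:
            status, value = STATUS_BELOW_LOQ, np.nan
        else:
            status, value = STATUS_QUANTIFIED, noisy
        rows.append(
            (r.station_id, float(r.x), float(r.y), r.substance, status, value, lod, loq)
        )
    return pd.DataFrame(
        rows, columns=["station_id", "x", "y", "substance", "status", "value", "LOD", "LOQ"]
    )
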