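"""Shared I/O and configuration for the exposure chain.

Rasters are exchanged as ESRI ASCII grids (text, lossless for float32 at the
printed precision used here), parcels as GeoJSON, tables as CSV, stage
manifests as JSON. The pipeline configuration is a YAML document validated
against a strict schema (unknown keys rejected, units documented per field);
defaults reproduce the standard synthetic study conditions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from shapely.geometry import mapping, shape

from .region import CROPS, Parcel, StudyRegion

__all__ = [
    "PipelineConfig",
    "default_config",
    "load_config",
    "validate_config",
    "read_grid",
    "write_grid",
    "write_parcels_geojson",
    "read_parcels_geojson",
]


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_grid(path, array: np.ndarray, origin=(0.0, 0.0), cell_size: float = 2000.0,
               nodata: float = -9999.0) -> None:
    """Write a (n_rows, n_cols) layer as an ESRI ASCII grid.

    Row 0 of ``array`` is the southernmost row (grid convention of the study
    region); the file stores rows north-to-south. Values are printed with 9
    significant digits, which round-trips float32 exactly.
    """
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("grid layer must be 2-D")
    n_rows, n_cols = arr.shape
    lines = [
        f"ncols {n_cols}",
        f"nrows {n_rows}",
        f"xllcorner {origin[0]:.6f}",
        f"yllcorner {origin[1]:.6f}",
        f"cellsize {cell_size:.6f}",
        f"NODATA_value {nodata:g}",
    ]
    body = np.where(np.isfinite(arr), arr, np.float32(nodata))
    for row in body[::-1]:
        lines.append(" ".join(np.format_float_scientific(v, precision=8) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_grid(path, expected_shape: tuple[int, int] | None = None):
    """Read an ESRI ASCII grid; returns ``(array, meta)`` with the array in
    south-to-north row order and NODATA as NaN."""
    lines = Path(path).read_text().splitlines()
    meta = {}
    k = 0
    while k < len(lines) and lines[k].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, val = lines[k].split()
        meta[key.lower()] = float(val)
        k += 1
    arr = np.loadtxt(lines[k:], dtype=np.float32)
    arr = np.atleast_2d(arr)[::-1].copy()
    if arr.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"grid body shape {arr.shape} inconsistent with header")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(f"grid shape {arr.shape} does not match region {expected_shape}")
    nodata = meta.get("nodata_value")
    if nodata is not None:
        arr[arr == np.float32(nodata)] = np.nan
    return arr, meta


# ---------------------------------------------------------------------------
# Parcel I/O (GeoJSON)
# ---------------------------------------------------------------------------

def write_parcels_geojson(path, parcels: list[Parcel]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {"id": p.id, "crop": p.crop, "annual_mass": p.annual_mass},
        }
        for p in parcels
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_parcels_geojson(path) -> list[Parcel]:
    doc = json.loads(Path(path).read_text())
    return [
        Parcel(
            id=f["properties"]["id"],
            polygon=shape(f["geometry"]),
            crop=f["properties"]["crop"],
            annual_mass={k: float(v) for k, v in f["properties"]["annual_mass"].items()},
        )
        for f in doc["features"]
    ]


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RegionCfg(_Strict):
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 2000.0  # m; 2000 m cells give the 4 km^2 support
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local metric grid"

    @field_validator("cell_size")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("[region].cell_size must be > 0")
        return v

    @field_validator("n_rows", "n_cols")
    @classmethod
    def _dims(cls, v):
        if v < 1:
            raise ValueError("[region] grid dimensions must be >= 1")
        return v


class ParcelsCfg(_Strict):
    n_parcels: int = 200
    min_side: float = 200.0  # m
    max_side: float = 800.0
    crop_mix: dict[str, float] = Field(
        default_factory=lambda: {"apple": 0.15, "lettuce": 0.15, "potato": 0.20,
                                 "tomato": 0.10, "cereal": 0.40}
    )
    n_municipalities: int = 12
    mean_municipality_pop: float = 5000.0

    @field_validator("crop_mix")
    @classmethod
    def _crops(cls, v):
        unknown = set(v) - set(CROPS)
        if unknown:
            raise ValueError(f"[parcels].crop_mix: unknown crops {sorted(unknown)}")
        return v


class SubstanceCfg(_Strict):
    mw: float  # g/mol
    mean_annual_mass_kg: float = 2.0  # lognormal mean of per-parcel annual mass
    v_d: float = 0.005  # particle dry-deposition velocity, m/s
    drift_gas_fraction: float = 0.5  # gas share of airborne drift
    k_vol_soil: float = 0.01  # 1/h
    k_vol_plant: float = 0.04  # 1/h
    soil_k_s: float = 0.023  # 1/d soil dissipation
    soil_baseline_median: float = 0.0  # mg/kg, legacy topsoil contamination
    water_baseline_median: float = 0.0  # ug/L tap-water level
    market_median: float = 0.0  # mg/kg fw true market residue (0 disables)
    market_sigma: float = 0.6  # lognormal sigma of market residues
    # PBPK substance overrides
    f_abs: float = 0.5
    f_m: float = 0.4
    cl_int: float = 80.0  # L/h

    @field_validator("drift_gas_fraction", "f_abs", "f_m")
    @classmethod
    def _frac(cls, v):
        if not (0 <= v <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        return v


class MetCfg(_Strict):
    prevailing_dir: float = 225.0
    dir_kappa: float = 1.5
    weibull_shape: float = 2.0
    weibull_scale: float = 4.5
    min_wind: float = 0.5
    temp_mean: float = 11.0
    temp_amplitude: float = 8.0
    temp_sigma: float = 2.5
    p_wet: float = 0.30
    mean_rain: float = 1.2
    mean_cloudiness: float = 5.0


class ApplicationsCfg(_Strict):
    events_per_parcel: int = 2
    # spreading windows in week indices (inclusive) per crop
    windows_weeks: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: {"apple": (14, 21), "lettuce": (10, 35),
                                 "potato": (16, 24), "tomato": (20, 28),
                                 "cereal": (12, 20)}
    )
    n_volat_steps: int = 4  # 3-h steps of post-application volatilization


class MonitoringCfg(_Strict):
    n_soil_stations: int = 30
    n_water_stations: int = 25
    noise_sigma: float = 0.3  # log-scale multiplicative measurement error
    soil_lod: float = 1e-4  # mg/kg
    soil_loq: float = 3e-4
    water_lod: float = 0.005  # ug/L
    water_loq: float = 0.015
    market_n_samples: int = 40
    market_lod: float = 0.005  # mg/kg fw
    market_loq: float = 0.015

    @model_validator(mode="after")
    def _lod_loq(self):
        for med in ("soil", "water", "market"):
            lod = getattr(self, f"{med}_lod")
            loq = getattr(self, f"{med}_loq")
            if not (loq >= lod > 0):
                raise ValueError(f"[monitoring].{med}_loq must satisfy LOQ >= LOD > 0")
        return self


class DispersionCfg(_Strict):
    source_height: float = 1.0  # m
    use_oracle: bool = False  # bypass the metamodel (exact teacher)
    n_met: int = 40
    n_receptors: int = 600
    max_range: float = 20000.0  # kernel truncation radius, m
    partition_mode: str = "wind_linear"


class GeostatCfg(_Strict):
    n_lags: int = 10
    max_lag_fraction: float = 0.5  # of the region diagonal
    log_transform: bool = False
    anisotropy_threshold: float = 1.5
    baseline_range_m: float = 20000.0  # spatial range of baseline truth fields
    baseline_sigma_log: float = 0.8
    aux_weights: dict[str, float] = Field(
        default_factory=lambda: {"emissions": 1.0, "population": 0.3, "altitude": 0.2}
    )


class ExposureCfg(_Strict):
    profile: str = "pregnant"
    body_weight: float = 67.0
    water_intake: float = 1.5
    soil_ingestion: float = 50.0
    inhalation_rate: float = 13.3
    food_intake: dict[str, float] = Field(
        default_factory=lambda: {"apple": 0.060, "lettuce": 0.030,
                                 "potato": 0.100, "tomato": 0.060}
    )
    self_consumption: dict[int, float] = Field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.12, 4: 0.03}
    )


class PBPKCfg(_Strict):
    n_compartments: int = 23
    k_u: float = 0.10
    urine_flow: float = 1.5
    mw_metabolite: float = 214.2  # 3-PBA


class PipelineConfig(_Strict):
    region: RegionCfg = Field(default_factory=RegionCfg)
    parcels: ParcelsCfg = Field(default_factory=ParcelsCfg)
    substances: dict[str, SubstanceCfg] = Field(
        default_factory=lambda: {
            "cypermethrin": SubstanceCfg(
                mw=416.3, mean_annual_mass_kg=3.0, soil_baseline_median=2e-3,
                water_baseline_median=0.010, market_median=4e-3,
                f_abs=0.5, f_m=0.40, cl_int=90.0,
            ),
            "deltamethrin": SubstanceCfg(
                mw=505.2, mean_annual_mass_kg=0.8, soil_baseline_median=5e-4,
                water_baseline_median=0.004, market_median=8e-4,
                f_abs=0.4, f_m=0.30, cl_int=70.0,
            ),
        }
    )
    met: MetCfg = Field(default_factory=MetCfg)
    applications: ApplicationsCfg = Field(default_factory=ApplicationsCfg)
    monitoring: MonitoringCfg = Field(default_factory=MonitoringCfg)
    dispersion: DispersionCfg = Field(default_factory=DispersionCfg)
    geostat: GeostatCfg = Field(default_factory=GeostatCfg)
    exposure: ExposureCfg = Field(default_factory=ExposureCfg)
    pbpk: PBPKCfg = Field(default_factory=PBPKCfg)
    weeks: int = 52
    scenarios: tuple[str, ...] = ("LB", "UB")

    @field_validator("scenarios")
    @classmethod
    def _scen(cls, v):
        bad = [s for s in v if s.upper() not in ("LB", "UB")]
        if bad:
            raise ValueError(f"scenarios must be LB/UB, got {bad}")
        return tuple(s.upper() for s in v)


def default_config(**overrides) -> PipelineConfig:
    """The standard synthetic study conditions; keyword overrides are merged
    shallowly per section."""
    cfg = PipelineConfig()
    if overrides:
        cfg = PipelineConfig(**{**cfg.model_dump(), **overrides})
    return cfg


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a raw mapping against the schema; every violation is reported
    with the path to the offending key (pydantic error format)."""
    return PipelineConfig(**raw)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)
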