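"""End-to-end chain orchestration and exposure-inequality indicators.

``run_chain`` executes the full source-to-internal-dose pipeline on the
synthetic region — applications, dispersion (metamodel over parcels),
geostatistical mapping of monitored media with LB/UB censoring scenarios,
multimedia transfer to soil and local foods, weekly dose aggregation and
PBPK conversion to urinary 3-PBA — and derives the inequality outputs:
annual-mean urinary maps per scenario, parent-compound contribution shares,
hotspot cells, a variogram-based grid-resolution diagnostic and
point-location estimation.

Stage outputs can be persisted to a directory as ``.npz`` arrays with JSON
manifests (configuration/seed hash, stage version), making a re-run resume
from any persisted stage; the chain is fully deterministic for a fixed
``(config, seed)``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dispersion as disp
from . import exposure as expo
from . import geostat, multimedia, pbpk
from .io_config import PipelineConfig, default_config
from .region import (
    MetParams,
    StudyRegion,
    generate_applications,
    generate_met,
    generate_region,
    sample_monitoring,
)

__all__ = [
    "run_chain",
    "ChainResult",
    "annual_mean",
    "hotspots",
    "resolution_diagnostic",
    "point_estimate",
]

STEPS_PER_WEEK = 56  # 3-h steps per week
MG_PER_KG = 1e6
MG_PER_NG = 1e-6


# ---------------------------------------------------------------------------
# Indicator operations
# ---------------------------------------------------------------------------

def annual_mean(weekly_cube: np.ndarray) -> np.ndarray:
    """Unweighted per-cell mean of 52 weekly layers."""
    cube = np.asarray(weekly_cube, dtype=float)
    if cube.shape[0] != 52:
        raise ValueError(f"annual mean needs 52 weekly layers, got {cube.shape[0]}")
    return cube.mean(axis=0)


def hotspots(indicator_map: np.ndarray, percentile: float) -> np.ndarray:
    """Indices (flat) of cells at or above the given percentile of the map's
    nonzero cells; ties are included. All-zero maps yield an empty set with a
    warning."""
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    vals = np.asarray(indicator_map, dtype=float).ravel()
    nz = vals[vals > 0]
    if nz.size == 0:
        warnings.warn("all-zero indicator map: no hotspots")
        return np.array([], dtype=int)
    thr = np.percentile(nz, percentile)
    return np.flatnonzero(vals >= thr)


def resolution_diagnostic(
    field2d: np.ndarray,
    cell_size: float,
    max_cells: int = 400,
    seed: int = 0,
) -> dict:
    """Variogram analysis of a gridded input field to recommend the coarsest
    grid resolution that still resolves its spatial structure.

    Fits a variogram to (a subsample of) the cell values and recommends the
    largest cell size not exceeding a quarter of the fitted range. Flat
    fields support any resolution; near-pure-nugget (white-noise) fields
    support none, reported with a warning.
    """
    arr = np.asarray(field2d, dtype=float)
    n_rows, n_cols = arr.shape
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    coords = np.column_stack([(jj.ravel() + 0.5), (ii.ravel() + 0.5)]) * cell_size
    vals = arr.ravel()
    if np.ptp(vals) < 1e-15 * max(1.0, np.abs(vals).max()):
        warnings.warn("flat field: any resolution is adequate")
        return {"recommended_cell_size": np.inf, "supported": True, "model": None}
    rng = np.random.default_rng(seed)
    if len(vals) > max_cells:
        idx = rng.choice(len(vals), size=max_cells, replace=False)
        coords, vals = coords[idx], vals[idx]
    diag = np.hypot(n_rows, n_cols) * cell_size
    bins = np.linspace(1e-9, 0.5 * diag, 13)
    emp = geostat.empirical_variogram(coords, vals, bins)
    model = geostat.fit_variogram(emp)
    nugget_share = model.nugget / max(model.sill, 1e-300)
    if model.range_ < 2 * cell_size or nugget_share > 0.8:
        warnings.warn(
            "near-pure-nugget field: no grid resolution resolves its structure"
        )
        return {"recommended_cell_size": 0.0, "supported": False, "model": model}
    return {
        "recommended_cell_size": model.range_ / 4.0,
        "supported": True,
        "model": model,
    }


def point_estimate(
    indicator_map: np.ndarray,
    region: StudyRegion,
    location: tuple[float, float],
    method: str = "kriging",
    model: geostat.VariogramModel | None = None,
    n_neighbors: int = 32,
):
    """Estimate an indicator at an arbitrary point from the cell-centre values.

    ``method='kriging'`` performs ordinary kriging from the nearest cell
    centres with a nugget-free variogram (the map is noise-free model output,
    so the estimator interpolates exactly at cell centres and returns a
    kriging variance); ``method='bilinear'`` interpolates without uncertainty.
    """
    x, y = location
    if not region.contains(x, y):
        raise ValueError(f"location {location} outside region bounds {region.bounds}")
    vals = np.asarray(indicator_map, dtype=float).ravel()
    centers = region.cell_centers()
    if method == "bilinear":
        from scipy.interpolate import RegularGridInterpolator

        x0, y0 = region.origin
        s = region.cell_size
        xi = x0 + (np.arange(region.n_cols) + 0.5) * s
        yi = y0 + (np.arange(region.n_rows) + 0.5) * s
        f = RegularGridInterpolator(
            (yi, xi), np.asarray(indicator_map, dtype=float),
            bounds_error=False, fill_value=None,
        )
        return float(f((np.clip(y, yi[0], yi[-1]), np.clip(x, xi[0], xi[-1])))), np.nan
    if model is None:
        diag = resolution_diagnostic(np.asarray(indicator_map, float), region.cell_size)
        m = diag["model"]
        if m is None:
            return float(vals.mean()), 0.0
        model = geostat.VariogramModel(
            m.family, 0.0, m.nugget + m.partial_sill, m.range_
        )
    d2 = ((centers - np.array([x, y])) ** 2).sum(axis=1)
    idx = np.argsort(d2)[: min(n_neighbors, len(vals))]
    pred, var = geostat.ordinary_kriging(
        centers[idx], vals[idx], model, np.array([[x, y]])
    )
    return float(pred[0]), float(var[0])


# ---------------------------------------------------------------------------
# Chain orchestration
# ---------------------------------------------------------------------------

@dataclass
class ChainResult:
    """All stage outputs of one end-to-end run."""

    config: PipelineConfig
    seed: int
    region: StudyRegion
    parcels: list
    population: object
    met: pd.DataFrame
    applications: pd.DataFrame
    weekly: dict  # substance -> {'c_gas','c_part','dep'} (n_weeks, n_cells)
    soil_maps: dict  # scenario -> substance -> (n_cells,) baseline mg/kg
    water_maps: dict  # scenario -> substance -> (n_cells,) ug/L
    market: dict  # substance -> group -> (LB, UB) mg/kg fw
    local_food: dict  # scenario -> substance -> group -> (n_cells,)
    doses: dict  # scenario -> substance -> {'ingestion','inhalation','c_inh'}
    urinary: dict  # scenario -> substance -> (n_weeks, n_cells) mg/L
    urinary_total: dict  # scenario -> (n_weeks, n_cells)
    annual_maps: dict  # scenario -> (n_rows, n_cols)
    contributions: dict  # scenario -> {substance: share}
    diagnostics: dict = field(default_factory=dict)


def _config_key(cfg: PipelineConfig, seed: int) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str) + f"|{seed}"
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _smooth_field(region: StudyRegion, rng: np.random.Generator,
                  range_m: float, n_bumps: int = 40) -> np.ndarray:
    """Unit-scale smooth random surface (sum of Gaussian bumps) used for the
    synthetic altitude and baseline contamination structure."""
    x0, y0, x1, y1 = region.bounds
    cx = rng.uniform(x0, x1, n_bumps)
    cy = rng.uniform(y0, y1, n_bumps)
    amp = rng.normal(0, 1, n_bumps)
    width = range_m / 2.0
    centers = region.cell_centers()
    f = np.zeros(region.n_cells)
    for k in range(n_bumps):
        d2 = (centers[:, 0] - cx[k]) ** 2 + (centers[:, 1] - cy[k]) ** 2
        f += amp[k] * np.exp(-0.5 * d2 / width**2)
    sd = f.std()
    return f / sd if sd > 0 else f


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _fit_sample_variogram(coords, values, fallback_range, n_lags=10):
    """Variogram of monitoring samples with a documented fallback when the
    empirical curve is unfittable (few stations, flat values)."""
    try:
        d = np.hypot(*(coords[:, None, :] - coords[None, :, :]).transpose(2, 0, 1))
        hmax = np.percentile(d[d > 0], 70)
        emp = geostat.empirical_variogram(
            coords, values, np.linspace(1e-9, hmax, n_lags + 1)
        )
        return geostat.fit_variogram(emp)
    except (ValueError, RuntimeError):
        var = float(np.var(values))
        return geostat.VariogramModel("spherical", 0.0, max(var, 1e-12), fallback_range)


def _stage(outdir, name, key, compute):
    """Persist/reload one stage as npz + JSON manifest (dict of arrays)."""
    if outdir is None:
        return compute()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / f"{name}.manifest.json"
    data_path = outdir / f"{name}.npz"
    if manifest.exists() and data_path.exists():
        meta = json.loads(manifest.read_text())
        if meta.get("key") == key:
            with np.load(data_path) as z:
                return {k: z[k] for k in z.files}
    out = compute()
    np.savez(data_path, **out)
    manifest.write_text(json.dumps({"stage": name, "key": key, "version": "1"}))
    return out


def run_chain(config: PipelineConfig | None = None, seed: int = 0,
              outdir: str | Path | None = None) -> ChainResult:
    """Execute the full exposure chain; deterministic for fixed (config, seed).

    When ``outdir`` is given, the dispersion fields, media maps and urinary
    cubes are persisted (npz + manifest) and reused by a subsequent run with
    the same configuration hash.
    """
    cfg = config or default_config()
    key = _config_key(cfg, seed)
    n_weeks = cfg.weeks
    n_steps = n_weeks * STEPS_PER_WEEK
    substances = sorted(cfg.substances)

    # --- stage 1: region, parcels, population -----------------------------
    region_cfg = {
        **cfg.region.model_dump(),
        **cfg.parcels.model_dump(),
        "mean_annual_mass_kg": {s: cfg.substances[s].mean_annual_mass_kg
                                for s in substances},
    }
    region, parcels, pop = generate_region(region_cfg, _sub_seed(seed, 1))
    n_cells = region.n_cells

    # --- stage 2: meteorology ---------------------------------------------
    met = generate_met(n_steps, MetParams(**cfg.met.model_dump()), _sub_seed(seed, 2))

    # --- stage 3: application schedule -------------------------------------
    windows = {
        crop: (w[0] * STEPS_PER_WEEK, min((w[1] + 1) * STEPS_PER_WEEK, n_steps) - 1)
        for crop, w in cfg.applications.windows_weeks.items()
    }
    apps = generate_applications(
        parcels, substances,
        {"events_per_parcel": cfg.applications.events_per_parcel, "windows": windows},
        _sub_seed(seed, 3),
    )

    # --- stage 4: dispersion -----------------------------------------------
    if cfg.dispersion.use_oracle:
        plume_model = disp.PlumeOracle(source_height=cfg.dispersion.source_height,
                                       min_wind=cfg.met.min_wind)
    else:
        plume_model = disp.fit_metamodel(
            {"n_met": cfg.dispersion.n_met, "n_receptors": cfg.dispersion.n_receptors,
             "source_height": cfg.dispersion.source_height,
             "x_range": (30.0, cfg.dispersion.max_range)},
            _sub_seed(seed, 4),
        )
    events, soil_input = _build_emissions(cfg, region, parcels, apps, met, n_steps, n_weeks)
    v_d = {s: cfg.substances[s].v_d for s in substances}

    def _compute_fields():
        out = disp.superpose_weekly(
            events, plume_model, met, region, v_d, n_weeks, STEPS_PER_WEEK
        )
        flat = {}
        for s in substances:
            for kname in ("c_gas", "c_part", "dep"):
                flat[f"{s}__{kname}"] = out.get(s, {}).get(
                    kname, np.zeros((n_weeks, n_cells))
                )
        return flat

    flat_fields = _stage(outdir, "dispersion", key, _compute_fields)
    weekly = {
        s: {kname: flat_fields[f"{s}__{kname}"] for kname in ("c_gas", "c_part", "dep")}
        for s in substances
    }

    # --- stage 5: geostatistical mapping of monitored media ----------------
    rng_geo = np.random.default_rng(_sub_seed(seed, 5))
    centers = region.cell_centers()
    altitude = 100.0 + 40.0 * _smooth_field(region, rng_geo, cfg.geostat.baseline_range_m)
    emissions_cell = _emissions_per_cell(region, parcels)
    w = cfg.geostat.aux_weights
    auxiliary = (
        w.get("emissions", 0.0) * _standardize(np.log1p(emissions_cell))
        + w.get("population", 0.0) * _standardize(np.log1p(pop.population.ravel()))
        + w.get("altitude", 0.0) * _standardize(altitude)
    )

    soil_maps: dict = {sc: {} for sc in cfg.scenarios}
    water_maps: dict = {sc: {} for sc in cfg.scenarios}
    mon = cfg.monitoring
    for medium, n_st, lod, loq, aux in (
        ("soil", mon.n_soil_stations, mon.soil_lod, mon.soil_loq, auxiliary),
        ("water", mon.n_water_stations, mon.water_lod, mon.water_loq, None),
    ):
        idx = rng_geo.choice(n_cells, size=min(n_st, n_cells), replace=False)
        st_xy = centers[idx]
        truth = {}
        for s in substances:
            med = (cfg.substances[s].soil_baseline_median if medium == "soil"
                   else cfg.substances[s].water_baseline_median)
            if med > 0:
                f = _smooth_field(region, rng_geo, cfg.geostat.baseline_range_m)
                truth[s] = np.exp(np.log(med) + cfg.geostat.baseline_sigma_log * f)
            else:
                truth[s] = np.zeros(n_cells)
        stations = pd.DataFrame(
            [
                (f"{medium[0].upper()}{k:03d}", st_xy[k, 0], st_xy[k, 1], s, lod, loq)
                for k in range(len(idx))
                for s in substances
            ],
            columns=["station_id", "x", "y", "substance", "LOD", "LOQ"],
        )
        samples = sample_monitoring(
            {s: truth[s].reshape(region.shape) for s in substances},
            stations, {"sigma": mon.noise_sigma}, region, _sub_seed(seed, 6),
        )
        for sc in cfg.scenarios:
            for s in substances:
                sub = samples[samples["substance"] == s]
                vals = geostat.censor_bounds(sub, sc).to_numpy()
                coords = sub[["x", "y"]].to_numpy(dtype=float)
                if len(vals) == 0:
                    est = np.zeros(n_cells)
                elif np.ptp(vals) < 1e-15:
                    est = np.full(n_cells, vals.mean() if len(vals) else 0.0)
                else:
                    vmod = _fit_sample_variogram(coords, vals, cfg.geostat.baseline_range_m)
                    if aux is not None:
                        aux_s = np.array([
                            aux[region.cell_index(x, y)[0] * region.n_cols
                                + region.cell_index(x, y)[1]]
                            for x, y in coords
                        ])
                        est, _ = geostat.external_drift_kriging(
                            coords, vals, vmod, aux_s, centers, aux
                        )
                    else:
                        est, _ = geostat.ordinary_kriging(coords, vals, vmod, centers)
                    est = np.maximum(est, 0.0)
                (soil_maps if medium == "soil" else water_maps)[sc][s] = est

    # --- stage 6: market-food LB/UB -----------------------------------------
    market = _market_residues(cfg, substances, _sub_seed(seed, 7))

    # --- stage 7: multimedia ------------------------------------------------
    local_food: dict = {sc: {} for sc in cfg.scenarios}
    soil_weekly: dict = {sc: {} for sc in cfg.scenarios}
    for sc in cfg.scenarios:
        for s in substances:
            scfg = cfg.substances[s]
            dep = weekly[s]["dep"]  # mg/m^2/d, (n_weeks, n_cells)
            app = soil_input[s]  # mg/m^2/d
            cell = multimedia.SoilCell(k_s=scfg.soil_k_s)
            c = soil_maps[sc][s].copy()
            series = np.zeros((n_weeks, n_cells))
            decay = np.exp(-cell.k_s * 7.0)
            gain = ((1.0 - decay) / cell.k_s if cell.k_s > 0 else 7.0) / (
                cell.bulk_density * cell.mixing_depth
            )
            for wk in range(n_weeks):
                c = c * decay + (dep[wk] + app[wk]) * gain
                series[wk] = c
            soil_weekly[sc][s] = series
            local_food[sc][s] = _harvest_concentrations(dep, series, n_weeks)

    # --- stage 8: weekly dose aggregation ------------------------------------
    urban_class = np.vectorize(expo.classify_urban_unit)(
        pop.urban_unit_size.ravel()
    )
    profile = expo.ExposureProfile(
        name=cfg.exposure.profile,
        body_weight=cfg.exposure.body_weight,
        food_intake=dict(cfg.exposure.food_intake),
        water_intake=cfg.exposure.water_intake,
        soil_ingestion=cfg.exposure.soil_ingestion,
        inhalation_rate=cfg.exposure.inhalation_rate,
    )
    doses: dict = {sc: {} for sc in cfg.scenarios}
    for sc in cfg.scenarios:
        for s in substances:
            media = {
                "c_gas": weekly[s]["c_gas"],
                "c_part": weekly[s]["c_part"],
                "c_soil": soil_weekly[sc][s],
                "c_water": water_maps[sc][s],
                "c_local": {g: np.broadcast_to(local_food[sc][s][g], (n_weeks, n_cells))
                            for g in expo.FOOD_GROUPS},
                "c_market": {g: market[s][g] for g in expo.FOOD_GROUPS},
            }
            tab = expo.weekly_dose_table(
                region.shape, media, urban_class, profile,
                self_consumption=cfg.exposure.self_consumption,
                market_scenarios=(sc,),
            )
            doses[sc][s] = {
                "ingestion": tab[f"ingestion_{sc}"],
                "inhalation": tab["inhalation"],
                "c_inh": tab["c_inh"],
            }

    # --- stage 9: PBPK -------------------------------------------------------
    urinary: dict = {sc: {} for sc in cfg.scenarios}
    urinary_total: dict = {}
    for sc in cfg.scenarios:
        def _compute_urinary(sc=sc):
            out = {}
            for s in substances:
                scfg = cfg.substances[s]
                params = pbpk.default_params(
                    cfg.pbpk.n_compartments, substance=s,
                    mw_parent=scfg.mw, f_abs=scfg.f_abs, f_m=scfg.f_m,
                    cl_int=scfg.cl_int, k_u=cfg.pbpk.k_u,
                    urine_flow=cfg.pbpk.urine_flow,
                    mw_metabolite=cfg.pbpk.mw_metabolite,
                    body_weight=cfg.exposure.body_weight,
                )
                model = pbpk.build_model(params)
                res = pbpk.simulate_cells(
                    model, doses[sc][s]["ingestion"], doses[sc][s]["c_inh"]
                )
                out[s] = res.urinary_conc_mg_L
            return out

        urinary[sc] = _stage(outdir, f"urinary_{sc.lower()}", key, _compute_urinary)
        urinary_total[sc] = sum(urinary[sc][s] for s in substances)

    # --- stage 10: indicators ------------------------------------------------
    annual_maps = {}
    contributions = {}
    for sc in cfg.scenarios:
        cube = urinary_total[sc]
        amap = (annual_mean(cube) if n_weeks == 52 else cube.mean(axis=0))
        annual_maps[sc] = amap.reshape(region.shape)
        mix = pbpk.mixture_contributions(
            {s: float(urinary[sc][s].sum()) for s in substances}
        )
        contributions[sc] = {s: mix["shares"][s] for s in substances} \
            if mix["defined"] else {s: np.nan for s in substances}

    diagnostics = {
        "config_key": key,
        "n_emission_events": int(len(events)),
        "metamodel_r2": getattr(plume_model, "heldout_r2", None),
    }
    return ChainResult(
        config=cfg, seed=seed, region=region, parcels=parcels, population=pop,
        met=met, applications=apps, weekly=weekly, soil_maps=soil_maps,
        water_maps=water_maps, market=market, local_food=local_food, doses=doses,
        urinary=urinary, urinary_total=urinary_total, annual_maps=annual_maps,
        contributions=contributions, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Chain helpers
# ---------------------------------------------------------------------------

def _build_emissions(cfg, region, parcels, apps, met, n_steps, n_weeks):
    """Partition applications and expand volatilization into emission events.

    Returns ``(events, soil_input)`` where events has columns
    ``x, y, timestep, substance, phase, mass_kg`` and ``soil_input`` maps
    substance -> (n_weeks, n_cells) areal application rate (mg/m^2/d) of the
    non-volatilized soil share.
    """
    pmodel = disp.PartitionModel(mode=cfg.dispersion.partition_mode)
    parcel_by_id = {p.id: p for p in parcels}
    cell_area = region.cell_size**2
    n_volat = cfg.applications.n_volat_steps
    soil_input = {s: np.zeros((n_weeks, region.n_cells)) for s in cfg.substances}
    rows = []
    for r in apps.itertuples():
        parcel = parcel_by_id[r.parcel_id]
        x, y = parcel.centroid
        scfg = cfg.substances[r.substance]
        fr = disp.partition_application(
            r.mass_kg, parcel.crop, met.iloc[int(r.timestep)], pmodel
        )
        drift = fr.f_drift * r.mass_kg
        gas = drift * scfg.drift_gas_fraction
        part = drift - gas
        if gas > 0:
            rows.append((x, y, int(r.timestep), r.substance, "gas", gas))
        if part > 0:
            rows.append((x, y, int(r.timestep), r.substance, "particle", part))
        # post-application volatilization from plant and soil stores
        plant_store = fr.f_plant * r.mass_kg
        soil_store = fr.f_soil * r.mass_kg
        for k in range(1, n_volat + 1):
            t = int(r.timestep) + k
            if t >= n_steps:
                break
            e_p, plant_store = disp.volatilization_flux(plant_store, scfg.k_vol_plant)
            e_s, soil_store = disp.volatilization_flux(soil_store, scfg.k_vol_soil)
            if e_p + e_s > 0:
                rows.append((x, y, t, r.substance, "gas", e_p + e_s))
        # non-volatilized soil share enters the topsoil of the source cell
        i, j = region.cell_index(x, y)
        week = min(int(r.timestep) // STEPS_PER_WEEK, n_weeks - 1)
        soil_input[r.substance][week, i * region.n_cols + j] += (
            soil_store * MG_PER_KG / cell_area / 7.0
        )
    events = pd.DataFrame(
        rows, columns=["x", "y", "timestep", "substance", "phase", "mass_kg"]
    )
    return events, soil_input


def _emissions_per_cell(region, parcels) -> np.ndarray:
    out = np.zeros(region.n_cells)
    for p in parcels:
        x, y = p.centroid
        if region.contains(x, y):
            i, j = region.cell_index(x, y)
            out[i * region.n_cols + j] += sum(p.annual_mass.values())
    return out


def _market_residues(cfg, substances, seed) -> dict:
    """Market-food (LB, UB) residue pairs from simulated censored residue
    surveys; a zero market median disables residues for that substance."""
    from .region import STATUS_BELOW_LOQ, STATUS_NON_DETECT, STATUS_QUANTIFIED

    rng = np.random.default_rng(seed)
    mon = cfg.monitoring
    market: dict = {}
    for s in substances:
        scfg = cfg.substances[s]
        market[s] = {}
        for g in expo.FOOD_GROUPS:
            if scfg.market_median <= 0 or mon.market_n_samples < 1:
                market[s][g] = (0.0, 0.0)
                continue
            draws = rng.lognormal(np.log(scfg.market_median), scfg.market_sigma,
                                  mon.market_n_samples)
            status = np.where(
                draws < mon.market_lod, STATUS_NON_DETECT,
                np.where(draws < mon.market_loq, STATUS_BELOW_LOQ, STATUS_QUANTIFIED),
            )
            df = pd.DataFrame({
                "status": status,
                "value": np.where(status == STATUS_QUANTIFIED, draws, np.nan),
                "LOD": mon.market_lod,
                "LOQ": mon.market_loq,
            })
            lb = float(geostat.censor_bounds(df, "LB").mean())
            ub = float(geostat.censor_bounds(df, "UB").mean())
            market[s][g] = (lb, ub)
    return market


def _harvest_concentrations(dep_weekly, soil_weekly, n_weeks) -> dict:
    """Edible-organ concentrations per food group for every cell (mg/kg fw),
    vectorized over cells via the shared weekly crop propagators."""
    out = {}
    for crop, params in multimedia.DEFAULT_CROPS.items():
        if crop not in expo.FOOD_GROUPS:
            continue
        w0, w1 = params.season
        w1 = min(w1, n_weeks - 1)
        weeks = np.arange(w0, w1 + 1)
        if len(weeks) == 0:
            out[crop] = np.zeros(dep_weekly.shape[1])
            continue
        phis, psis = multimedia.crop_propagators(params, weeks)
        n_comp = len(params.compartments)
        n_cells = dep_weekly.shape[1]
        m = np.zeros((n_comp, n_cells))
        ei = params.compartments.index(params.edible)
        if crop == "lettuce":
            lai = np.array([params.lai(int(w)) for w in weeks])
            weekly_conc = np.zeros((len(weeks), n_cells))
            for k, wk in enumerate(weeks):
                u = np.vstack([np.maximum(dep_weekly[wk], 0.0),
                               np.maximum(soil_weekly[wk], 0.0)])
                m = phis[k] @ m + psis[k] @ u
                b = float(params.biomass[params.edible](int(wk)))
                weekly_conc[k] = m[ei] / b if b > 0 else 0.0
            tot = lai.sum()
            out[crop] = (lai / tot) @ weekly_conc if tot > 0 else weekly_conc.mean(axis=0)
        else:
            for k, wk in enumerate(weeks):
                u = np.vstack([np.maximum(dep_weekly[wk], 0.0),
                               np.maximum(soil_weekly[wk], 0.0)])
                m = phis[k] @ m + psis[k] @ u
            b = float(params.biomass[params.edible](int(w1)))
            out[crop] = m[ei] / b if b > 0 else np.zeros(n_cells)
        out[crop] = np.maximum(out[crop], 0.0)
    return out
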