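"""Emissions partitioning and atmospheric dispersion on the reference grid.

Each tri-hourly application is partitioned among soil, plant and airborne
drift; soil and plant stores subsequently volatilize with first-order
kinetics. Airborne emissions are dispersed with a steady-state Gaussian plume
(Pasquill-Gifford sigma curves, Briggs open-country form, ground reflection)
that serves as the in-repo teacher for a fast statistical metamodel: the
learner maps (met features, wind-aligned receptor offsets) to per-unit-rate
dilution, and per-event fields are superposed linearly over all parcels.
The substance is treated as a passive tracer: no chemical transformation
after emission; gas and particle phases are tracked independently, particles
deposit with a constant dry-deposition velocity.

Units: emissions in kg per 3-h step; air concentrations in ng/m^3;
deposition in ng/m^2 per 3-h step.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .region import StudyRegion

__all__ = [
    "PartitionFractions",
    "PartitionModel",
    "partition_application",
    "volatilization_flux",
    "PlumeOracle",
    "DispersionMetamodel",
    "fit_metamodel",
    "superpose",
    "ConcDepositionField",
    "STEP_SECONDS",
]

STEP_SECONDS = 10800.0  # one 3-h step
KG_TO_NG = 1e12

STABILITY_CLASSES = "ABCDEF"

# Briggs (open country) dispersion coefficients: sigma_y = a*x/sqrt(1+1e-4 x);
# sigma_z per-class rational forms, x in metres.
_BRIGGS_Y = {"A": 0.22, "B": 0.16, "C": 0.11, "D": 0.08, "E": 0.06, "F": 0.04}


def _sigma_y(cls: str, x: np.ndarray) -> np.ndarray:
    return _BRIGGS_Y[cls] * x / np.sqrt(1.0 + 1e-4 * x)


def _sigma_z(cls: str, x: np.ndarray) -> np.ndarray:
    if cls == "A":
        return 0.20 * x
    if cls == "B":
        return 0.12 * x
    if cls == "C":
        return 0.08 * x / np.sqrt(1.0 + 2e-4 * x)
    if cls == "D":
        return 0.06 * x / np.sqrt(1.0 + 1.5e-3 * x)
    if cls == "E":
        return 0.03 * x / (1.0 + 3e-4 * x)
    return 0.016 * x / (1.0 + 3e-4 * x)


@dataclass(frozen=True)
class PartitionFractions:
    """Fractions of an application reaching soil, plant canopy and air drift
    in the first minutes after spreading; they always sum to one."""

    f_soil: float
    f_plant: float
    f_drift: float

    def __post_init__(self) -> None:
        for name, f in (("f_soil", self.f_soil), ("f_plant", self.f_plant),
                        ("f_drift", self.f_drift)):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} = {f} outside [0, 1]")
        if abs(self.f_soil + self.f_plant + self.f_drift - 1.0) > 1e-12:
            raise ValueError("partition fractions must sum to 1")


# Illustrative per-crop base partition (soil, plant, drift) at reference wind
# 3 m/s; dense canopies intercept more, bare-row crops send more to soil.
_DEFAULT_PARTITION = {
    "apple": (0.30, 0.55, 0.15),
    "lettuce": (0.45, 0.45, 0.10),
    "potato": (0.50, 0.42, 0.08),
    "tomato": (0.40, 0.50, 0.10),
    "cereal": (0.35, 0.55, 0.10),
}


@dataclass
class PartitionModel:
    """Soil/plant/drift partition rule.

    ``mode='constant'`` returns the configured per-crop table exactly;
    ``mode='wind_linear'`` scales the drift fraction linearly with wind speed
    around the 3 m/s reference (capped at ``drift_cap``) and renormalizes the
    soil and plant shares proportionally, so drift is nondecreasing in wind.
    """

    mode: str = "wind_linear"
    table: dict = field(default_factory=lambda: dict(_DEFAULT_PARTITION))
    wind_ref: float = 3.0
    drift_cap: float = 0.5

    def fractions(self, crop: str, wind_speed: float) -> PartitionFractions:
        if crop not in self.table:
            raise ValueError(f"unknown crop {crop!r}: no partition entry")
        s, p, d = self.table[crop]
        tot = s + p + d
        if abs(tot - 1.0) > 1e-12:
            s, p, d = s / tot, p / tot, d / tot
        if self.mode == "constant":
            return PartitionFractions(s, p, d)
        d_new = min(self.drift_cap, d * max(wind_speed, 0.0) / self.wind_ref)
        rest = 1.0 - d_new
        sp = s + p
        return PartitionFractions(s / sp * rest, p / sp * rest, d_new)


def partition_application(event_mass: float, crop: str, met: pd.Series | dict,
                          model: PartitionModel | None = None) -> PartitionFractions:
    """Partition one application among soil, plant and drift for the given
    meteorological record (only wind speed matters under the default rule)."""
    if event_mass < 0:
        raise ValueError("event mass must be >= 0")
    model = model or PartitionModel()
    u = float(met["wind_speed"]) if not np.isscalar(met) else float(met)
    return model.fractions(crop, u)


def volatilization_flux(store: float, k_vol: float, dt: float = 3.0):
    """First-order volatilization from a soil or plant store over ``dt`` hours.

    Returns ``(emitted, new_store)`` with emitted = store*(1 - exp(-k_vol*dt));
    mass is conserved exactly.
    """
    if store < 0:
        raise ValueError(f"negative store: {store}")
    if k_vol < 0:
        raise ValueError("k_vol must be >= 0")
    emitted = store * (1.0 - np.exp(-k_vol * dt))
    return emitted, store - emitted


# ---------------------------------------------------------------------------
# Plume oracle
# ---------------------------------------------------------------------------

@dataclass
class PlumeOracle:
    """Steady-state Gaussian plume for a unit-rate ground-area source,
    receptor at ground level, with full ground reflection:

        C(x, y) = Q / (2 pi u sy sz) * exp(-y^2 / 2 sy^2) * 2 exp(-H^2 / 2 sz^2)

    ``dilution`` returns C/Q in s/m^3; receptors upwind of the source get 0.
    The dry-deposition factor for particles is ``v_d * dilution``.
    """

    source_height: float = 1.0  # m, spray-boom release height
    min_wind: float = 0.5

    def dilution_aligned(self, downwind: np.ndarray, crosswind: np.ndarray,
                         wind_speed: float, stability: str) -> np.ndarray:
        """Dilution (s/m^3) at wind-aligned offsets (downwind x, crosswind y)."""
        if stability not in STABILITY_CLASSES:
            raise ValueError(f"stability class must be one of {STABILITY_CLASSES}")
        u = max(float(wind_speed), self.min_wind)
        x = np.asarray(downwind, dtype=float)
        y = np.asarray(crosswind, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        ok = x > 0
        if not np.any(ok):
            return out
        xs = np.where(ok, x, 1.0)
        sy = _sigma_y(stability, xs)
        sz = _sigma_z(stability, xs)
        c = (
            1.0 / (2.0 * np.pi * u * sy * sz)
            * np.exp(-0.5 * (y / sy) ** 2)
            * 2.0
            * np.exp(-0.5 * (self.source_height / sz) ** 2)
        )
        out[ok] = np.broadcast_to(c, out.shape)[ok]
        return out

    def dilution(self, dx: np.ndarray, dy: np.ndarray, wind_speed: float,
                 wind_dir: float, stability: str) -> np.ndarray:
        """Dilution at map offsets (dx east, dy north) from the source for a
        wind blowing FROM ``wind_dir`` degrees (meteorological convention)."""
        beta = np.radians((wind_dir + 180.0) % 360.0)  # direction of travel
        fx, fy = np.sin(beta), np.cos(beta)  # bearing -> map unit vector
        down = dx * fx + dy * fy
        cross = -dx * fy + dy * fx
        return self.dilution_aligned(down, cross, wind_speed, stability)

    # shared predict interface with the metamodel
    def predict_dilution(self, dx, dy, wind_speed, wind_dir, stability):
        return self.dilution(dx, dy, wind_speed, wind_dir, stability)

    def cell_integrated(self, dx, dy, wind_speed, wind_dir, stability,
                        cell_size: float, n_sub: int = 5) -> np.ndarray:
        """Cell-averaged dilution by n_sub x n_sub midpoint quadrature."""
        offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
        acc = np.zeros(np.broadcast(np.asarray(dx, float), np.asarray(dy, float)).shape)
        for ox in offs:
            for oy in offs:
                acc += self.dilution(
                    np.asarray(dx) + ox * cell_size,
                    np.asarray(dy) + oy * cell_size,
                    wind_speed, wind_dir, stability,
                )
        return acc / n_sub**2


# ---------------------------------------------------------------------------
# Metamodel
# ---------------------------------------------------------------------------

_LOG_FLOOR = -30.0  # log10 dilution below which the plume is treated as zero


@dataclass
class DispersionMetamodel:
    """Statistical emulator of the plume oracle.

    Trained on a database of single-parcel unit-rate simulations sampled over
    met conditions and wind-aligned receptor offsets; predicts log10 dilution
    from (log10 downwind, crosswind/downwind, wind speed, stability index).
    Mass/emission-rate scaling is applied outside the learner, so predicted
    fields are exactly linear in emitted mass.
    """

    estimator: object
    source_height: float
    min_wind: float
    heldout_r2: float
    training_hash: str
    version: str = "1"
    max_range: float = 30000.0
    max_cross_sigmas: float = 4.0  # trained crosswind extent; beyond it the kernel is ~0
    train_sample: tuple | None = None  # (X, y) subset of the training database

    @staticmethod
    def _features(down, cross, stab_idx):
        # crosswind offset normalized by the class plume width sigma_y(x):
        # in these coordinates the log-dilution surface is smooth and the
        # tree ensemble interpolates it accurately far off-axis too. The
        # teacher scales exactly as 1/u, so wind speed is factored out of the
        # learned target (log10 of u times dilution) rather than learned.
        down = np.asarray(down, dtype=float)
        stab = STABILITY_CLASSES[int(stab_idx)]
        sy = _sigma_y(stab, np.maximum(down, 1.0))
        return np.column_stack([
            np.log10(np.maximum(down, 1.0)),
            np.abs(np.asarray(cross, dtype=float)) / sy,
            np.broadcast_to(np.asarray(stab_idx, dtype=float), down.shape).ravel(),
        ])

    def predict_dilution(self, dx, dy, wind_speed, wind_dir, stability) -> np.ndarray:
        beta = np.radians((wind_dir + 180.0) % 360.0)
        fx, fy = np.sin(beta), np.cos(beta)
        dx = np.asarray(dx, dtype=float)
        dy = np.asarray(dy, dtype=float)
        down = dx * fx + dy * fy
        cross = -dx * fy + dy * fx
        out = np.zeros(down.shape)
        stab_char = stability
        sy = _sigma_y(stab_char, np.maximum(down, 1.0))
        ok = (
            (down > 1.0)
            & (down <= self.max_range)
            & (np.abs(cross) <= self.max_cross_sigmas * sy)
        )
        if not ok.any():
            return out
        X = self._features(down[ok], cross[ok], STABILITY_CLASSES.index(stability))
        logd = self.estimator.predict(X)
        u = max(float(wind_speed), self.min_wind)
        out[ok] = np.where(logd > _LOG_FLOOR, 10.0 ** logd / u, 0.0)
        return out

    def metadata(self) -> dict:
        return {
            "version": self.version,
            "training_hash": self.training_hash,
            "heldout_r2": self.heldout_r2,
            "source_height": self.source_height,
            "min_wind": self.min_wind,
            "max_range": self.max_range,
        }

    def save(self, path) -> None:
        """Persist the learner (joblib binary) with a JSON metadata sidecar."""
        import joblib

        joblib.dump(self, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2)

    @staticmethod
    def load(path) -> "DispersionMetamodel":
        import joblib

        return joblib.load(path)


def fit_metamodel(training_config: dict | None = None, seed: int = 0) -> DispersionMetamodel:
    """Learn the dispersion metamodel from plume-oracle simulations.

    ``training_config`` keys (defaults): ``n_met`` met-condition samples (40),
    ``n_receptors`` receptor offsets per condition (600), ``wind_range``
    ((0.5, 12) m/s), ``x_range`` ((30, 30000) m downwind, log-uniform),
    ``source_height`` (1 m), ``holdout`` fraction (0.2).

    The held-out R^2 (log10-dilution scale) against the oracle is stored on
    the returned model; a degenerate training set (a single met condition)
    is refused.
    """
    from sklearn.ensemble import ExtraTreesRegressor
    from sklearn.metrics import r2_score

    cfg = dict(training_config or {})
    n_met = int(cfg.get("n_met", 40))
    n_rec = int(cfg.get("n_receptors", 600))
    u_lo, u_hi = cfg.get("wind_range", (0.5, 12.0))
    x_lo, x_hi = cfg.get("x_range", (30.0, 30000.0))
    H = float(cfg.get("source_height", 1.0))
    holdout = float(cfg.get("holdout", 0.2))
    if n_met < 2:
        raise ValueError(
            f"degenerate training set: {n_met} met condition(s); need >= 2 to generalize"
        )
    rng = np.random.default_rng(seed)
    oracle = PlumeOracle(source_height=H)

    rows_X, rows_y = [], []
    for _ in range(n_met):
        u = rng.uniform(u_lo, u_hi)
        stab_idx = rng.integers(0, len(STABILITY_CLASSES))
        stab = STABILITY_CLASSES[stab_idx]
        x = np.exp(rng.uniform(np.log(x_lo), np.log(x_hi), n_rec))
        # crosswind: half the receptors on the centerline (the kernel peak),
        # half spread out to four plume widths (symmetric kernel)
        y = rng.uniform(0.0, 4.0, n_rec) * _sigma_y(stab, x)
        y[: n_rec // 2] = 0.0
        dil = oracle.dilution_aligned(x, y, u, stab)
        keep = dil > 10.0 ** _LOG_FLOOR
        rows_X.append(DispersionMetamodel._features(x[keep], y[keep], stab_idx))
        rows_y.append(np.log10(dil[keep] * u))
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)

    n = len(y)
    perm = rng.permutation(n)
    n_test = max(1, int(round(holdout * n)))
    test, train = perm[:n_test], perm[n_test:]
    est = ExtraTreesRegressor(
        n_estimators=int(cfg.get("n_estimators", 60)),
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
        bootstrap=False,
    )
    est.fit(X[train], y[train])
    r2 = float(r2_score(y[test], est.predict(X[test])))
    est.fit(X, y)  # final model on the full database
    th = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16]
    keep = rng.choice(n, size=min(200, n), replace=False)
    return DispersionMetamodel(
        estimator=est,
        source_height=H,
        min_wind=u_lo,
        heldout_r2=r2,
        training_hash=th,
        max_range=float(x_hi),
        train_sample=(X[keep], y[keep]),
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class ConcDepositionField:
    """Per-cell, per-3h-step, per-substance gas/particle air concentrations
    (ng/m^3) and surface deposition (ng/m^2 per step); linear in emitted
    mass and non-negative by construction."""

    region: StudyRegion
    n_steps: int
    substances: list[str]
    c_gas: dict[str, np.ndarray]  # substance -> (n_steps, n_rows, n_cols)
    c_part: dict[str, np.ndarray]
    deposition: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, region: StudyRegion, n_steps: int, substances: list[str]):
        shape = (n_steps, region.n_rows, region.n_cols)
        return cls(
            region=region,
            n_steps=n_steps,
            substances=list(substances),
            c_gas={s: np.zeros(shape) for s in substances},
            c_part={s: np.zeros(shape) for s in substances},
            deposition={s: np.zeros(shape) for s in substances},
        )


def superpose(
    events: pd.DataFrame,
    model,
    met_series: pd.DataFrame,
    region: StudyRegion,
    v_d: dict[str, float],
    n_steps: int | None = None,
) -> ConcDepositionField:
    """Linear superposition of per-event plume kernels over all parcels.

    ``events`` columns: ``x, y`` (source location), ``timestep``, ``substance``,
    ``phase`` ('gas'|'particle'), ``mass_kg``. ``model`` is any object with a
    ``predict_dilution(dx, dy, wind_speed, wind_dir, stability)`` method (the
    metamodel or the oracle itself). Events outside the region are skipped
    with a warning and counted. Particle deposition uses the per-substance
    dry-deposition velocity ``v_d`` (m/s).
    """
    if n_steps is None:
        n_steps = len(met_series)
    substances = sorted(events["substance"].unique()) if len(events) else []
    field_out = ConcDepositionField.zeros(region, n_steps, substances)
    if len(events) == 0:
        return field_out
    if events["timestep"].max() >= len(met_series):
        raise ValueError("event timestep outside the meteorological series span")

    centers = region.cell_centers()
    skipped = 0
    met_idx = met_series.set_index("timestep")
    # evaluate one kernel per unique (source, step); reuse across phases/substances
    for (x, y, t), grp in events.groupby(["x", "y", "timestep"], sort=True):
        if not region.contains(float(x), float(y)):
            skipped += len(grp)
            continue
        met = met_idx.loc[int(t)]
        dil = model.predict_dilution(
            centers[:, 0] - float(x),
            centers[:, 1] - float(y),
            float(met["wind_speed"]),
            float(met["wind_dir"]),
            str(met["stability_class"]),
        ).reshape(region.shape)
        # unit fields per kg emitted; the event mass multiplies last, so the
        # superposed field is exactly linear in emitted mass
        unit_conc = dil * (KG_TO_NG / STEP_SECONDS)  # ng/m^3 per kg
        for r in grp.itertuples():
            if r.phase == "gas":
                field_out.c_gas[r.substance][int(t)] += r.mass_kg * unit_conc
            else:
                field_out.c_part[r.substance][int(t)] += r.mass_kg * unit_conc
                field_out.deposition[r.substance][int(t)] += r.mass_kg * (
                    unit_conc * (v_d.get(r.substance, 0.0) * STEP_SECONDS)
                )
    if skipped:
        warnings.warn(f"skipped {skipped} emission events outside the region")
    return field_out


def superpose_weekly(
    events: pd.DataFrame,
    model,
    met_series: pd.DataFrame,
    region: StudyRegion,
    v_d: dict[str, float],
    n_weeks: int,
    steps_per_week: int = 56,
) -> dict[str, dict[str, np.ndarray]]:
    """Superposition aggregated directly to weekly support (memory-light).

    Same inputs as :func:`superpose`. Returns ``substance -> {'c_gas',
    'c_part', 'dep'}`` arrays of shape (n_weeks, n_cells): gas/particle
    concentrations are week-averaged (ng/m^3) and deposition is the weekly
    total converted to an areal daily rate (mg/m^2/d). One kernel is
    evaluated per unique (source, step) pair and shared across phases and
    substances.
    """
    substances = sorted(events["substance"].unique()) if len(events) else []
    n_cells = region.n_cells
    out = {
        s: {k: np.zeros((n_weeks, n_cells)) for k in ("c_gas", "c_part", "dep")}
        for s in substances
    }
    if len(events) == 0:
        return out
    if events["timestep"].max() >= len(met_series):
        raise ValueError("event timestep outside the meteorological series span")
    centers = region.cell_centers()
    met_idx = met_series.set_index("timestep")
    skipped = 0
    mg_per_ng = 1e-6
    for (x, y, t), grp in events.groupby(["x", "y", "timestep"], sort=True):
        if not region.contains(float(x), float(y)):
            skipped += len(grp)
            continue
        week = int(t) // steps_per_week
        if week >= n_weeks:
            continue
        met = met_idx.loc[int(t)]
        dil = model.predict_dilution(
            centers[:, 0] - float(x),
            centers[:, 1] - float(y),
            float(met["wind_speed"]),
            float(met["wind_dir"]),
            str(met["stability_class"]),
        )
        if not np.any(dil):
            continue
        unit_conc = dil * (KG_TO_NG / STEP_SECONDS)  # ng/m^3 per kg emitted
        for r in grp.itertuples():
            conc = r.mass_kg * unit_conc
            if r.phase == "gas":
                out[r.substance]["c_gas"][week] += conc / steps_per_week
            else:
                out[r.substance]["c_part"][week] += conc / steps_per_week
                # ng/m^2 over the step -> mg/m^2/d averaged over the week
                out[r.substance]["dep"][week] += (
                    v_d.get(r.substance, 0.0) * conc * STEP_SECONDS * mg_per_ng / 7.0
                )
    if skipped:
        warnings.warn(f"skipped {skipped} emission events outside the region")
    return out
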