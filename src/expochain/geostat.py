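"""Geostatistical mapping of sparse, censored monitoring data.

Implements the spatial toolbox used to carry point measurements onto the
reference grid: empirical 2D variograms with directional binning and an
anisotropy test, weighted-least-squares variogram fitting, ordinary kriging,
external-drift kriging (mean affine in an auxiliary covariate), hybrid
regression-kriging with a tree-ensemble trend, lower/upper-bound substitution
rules for censored measurements, and a bootstrap EM estimator for left-censored
multivariate lognormal samples.

Conventions
-----------
* Semivariogram formulation throughout; the kriging systems are solved
  globally for n <= 500 samples and on the 32 nearest neighbours otherwise.
* Concentrations are usually mapped on the log scale upstream of these
  functions; the helpers here are scale-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, spatial
from scipy.special import log_ndtr, ndtri
from scipy.stats import multivariate_normal, norm

from .region import STATUS_BELOW_LOQ, STATUS_NON_DETECT, STATUS_QUANTIFIED

__all__ = [
    "VariogramModel",
    "empirical_variogram",
    "test_anisotropy",
    "fit_variogram",
    "ordinary_kriging",
    "external_drift_kriging",
    "regression_kriging",
    "censor_bounds",
    "impute_censored_em",
    "simulate_gaussian_field",
]

_FAMILIES = ("spherical", "exponential", "gaussian")

GLOBAL_NEIGHBORHOOD_MAX = 500
N_NEIGHBORS = 32


@dataclass
class VariogramModel:
    """Parametric semivariogram gamma(h) = nugget + partial_sill * g(h/range).

    ``anisotropy_ratio`` (minor/major range, in (0, 1]) and ``anisotropy_angle``
    (degrees, orientation of the major axis, counterclockwise from east)
    describe geometric anisotropy handled by coordinate rotation + scaling.
    """

    family: str = "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 1000.0
    anisotropy_ratio: float = 1.0
    anisotropy_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")
        if not (0 < self.anisotropy_ratio <= 1):
            raise ValueError("anisotropy_ratio must be in (0, 1]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def _structure(self, h: np.ndarray) -> np.ndarray:
        r = h / self.range_
        if self.family == "spherical":
            g = np.where(r < 1, 1.5 * r - 0.5 * r**3, 1.0)
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * r)  # practical range convention
        else:  # gaussian
            g = 1.0 - np.exp(-3.0 * r**2)
        return g

    def gamma(self, h) -> np.ndarray:
        """Semivariance at (isotropic-equivalent) lag distance h; gamma(0) = 0."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * self._structure(h)
        return np.where(h > 0, g, 0.0)

    def transform_coords(self, coords: np.ndarray) -> np.ndarray:
        """Rotate/scale coordinates so the model becomes isotropic."""
        if self.anisotropy_ratio == 1.0:
            return np.asarray(coords, dtype=float)
        a = np.radians(self.anisotropy_angle)
        rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        t = np.asarray(coords, dtype=float) @ rot.T
        t[:, 1] /= self.anisotropy_ratio
        return t


# ---------------------------------------------------------------------------
# Empirical variogram + anisotropy
# ---------------------------------------------------------------------------

def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    lag_bins: np.ndarray,
    directions: list[float] | None = None,
    angle_tol: float | None = None,
) -> pd.DataFrame:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) per lag bin.

    ``lag_bins`` are strictly increasing bin edges. ``directions`` (degrees,
    counterclockwise from east) selects pairs whose separation azimuth lies
    within ``angle_tol`` of the direction (default 90/len tolerance);
    ``None`` computes the omnidirectional variogram.

    Returns a DataFrame with ``direction, lag, gamma, n_pairs`` (``direction``
    is NaN for the omnidirectional case; empty bins are dropped).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples for an empirical variogram")
    lag_bins = np.asarray(lag_bins, dtype=float)
    if np.any(np.diff(lag_bins) <= 0):
        raise ValueError("lag_bins must be strictly increasing")

    iu, ju = np.triu_indices(len(values), k=1)
    dvec = coords[ju] - coords[iu]
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    sq = (values[iu] - values[ju]) ** 2
    azimuth = np.degrees(np.arctan2(dvec[:, 1], dvec[:, 0])) % 180.0

    dir_list: list[float | None] = [None] if directions is None else list(directions)
    if angle_tol is None and directions is not None:
        angle_tol = 90.0 / len(directions)

    records = []
    for d in dir_list:
        if d is None:
            sel = np.ones(len(dist), dtype=bool)
        else:
            diff = np.abs((azimuth - (d % 180.0) + 90.0) % 180.0 - 90.0)
            sel = diff <= angle_tol
        which = np.digitize(dist[sel], lag_bins) - 1
        for b in range(len(lag_bins) - 1):
            m = which == b
            n = int(m.sum())
            if n == 0:
                continue
            records.append(
                (
                    np.nan if d is None else float(d),
                    0.5 * (lag_bins[b] + lag_bins[b + 1]),
                    float(sq[sel][m].sum() / (2.0 * n)),
                    n,
                )
            )
    return pd.DataFrame(records, columns=["direction", "lag", "gamma", "n_pairs"])


def fit_variogram(
    empirical: pd.DataFrame,
    family: str = "auto",
) -> VariogramModel:
    """Fit a variogram model to binned semivariances by weighted least squares.

    Weights follow the Cressie scheme N(h)/gamma_model(h)^2, iterated inside
    the optimiser. ``family='auto'`` picks the best of spherical/exponential
    by the achieved WLS objective. Degenerate (pure-nugget) data converge to
    partial_sill ~ 0 with the range pinned near its lower bound.
    """
    emp = empirical.dropna(subset=["gamma"])
    lags = emp["lag"].to_numpy(dtype=float)
    gammas = emp["gamma"].to_numpy(dtype=float)
    npairs = emp["n_pairs"].to_numpy(dtype=float)
    if len(lags) < 3:
        raise ValueError("need >= 3 non-empty lag bins to fit a variogram")

    families = [family] if family != "auto" else ["spherical", "exponential"]
    gmax = max(gammas.max(), 1e-12)
    hmax = lags.max()

    def _objective(theta, fam):
        nugget, psill, rng_ = theta
        model = VariogramModel(fam, max(nugget, 0), max(psill, 1e-15), max(rng_, 1e-9))
        pred = model.gamma(lags)
        w = npairs / np.maximum(pred, 1e-3 * gmax) ** 2
        return np.sqrt(w) * (pred - gammas)

    best: tuple[float, VariogramModel] | None = None
    for fam in families:
        x0 = np.array([0.1 * gmax, 0.9 * gmax, 0.5 * hmax])
        try:
            res = optimize.least_squares(
                _objective,
                x0,
                args=(fam,),
                bounds=([0.0, 0.0, 1e-6 * hmax], [2 * gmax, 4 * gmax, 10 * hmax]),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            raise RuntimeError(f"variogram fit failed for family {fam}: {exc}")
        cost = float(res.cost)
        model = VariogramModel(
            fam,
            float(max(res.x[0], 0.0)),
            float(max(res.x[1], 0.0)),
            float(max(res.x[2], 1e-9)),
        )
        if best is None or cost < best[0]:
            best = (cost, model)
    assert best is not None
    return best[1]


def test_anisotropy(
    directional_variograms: pd.DataFrame,
    threshold: float = 1.5,
    family: str = "auto",
) -> dict:
    """Compare fitted ranges across directions and declare geometric anisotropy
    when the max/min range ratio exceeds ``threshold``.

    Input is the output of :func:`empirical_variogram` with >= 2 directions.
    Returns ``{'anisotropic': bool, 'ratio': float, 'angle': float,
    'ranges': {direction: range}}``; unfittable directions fall back to the
    isotropic verdict with a warning.
    """
    dirs = sorted(d for d in directional_variograms["direction"].dropna().unique())
    if len(dirs) < 2:
        raise ValueError("need >= 2 directions to test anisotropy")
    ranges: dict[float, float] = {}
    for d in dirs:
        sub = directional_variograms[directional_variograms["direction"] == d]
        try:
            ranges[d] = fit_variogram(sub, family=family).range_
        except (ValueError, RuntimeError) as exc:
            warnings.warn(
                f"direction {d}: variogram unfittable ({exc}); assuming isotropy"
            )
            return {"anisotropic": False, "ratio": 1.0, "angle": 0.0, "ranges": ranges}
    rmax = max(ranges.values())
    rmin = min(ranges.values())
    ratio = rmax / max(rmin, 1e-12)
    angle = max(ranges, key=ranges.get)
    return {
        "anisotropic": bool(ratio > threshold),
        "ratio": float(ratio),
        "angle": float(angle),
        "ranges": ranges,
    }


# ---------------------------------------------------------------------------
# Kriging
# ---------------------------------------------------------------------------

def _dedup(coords: np.ndarray, values: np.ndarray, drift: np.ndarray | None):
    """Average values at duplicate locations (singular-system guard)."""
    key = np.round(coords, 6)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    if len(idx) == len(coords):
        return coords, values, drift
    warnings.warn("duplicate sample locations detected; averaging values")
    n = len(idx)
    out_v = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(out_v, inv, values)
    np.add.at(counts, inv, 1.0)
    out_c = coords[idx]
    out_d = drift[idx] if drift is not None else None
    return out_c, out_v / counts, out_d


def _krige_system(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    drift: np.ndarray | None = None,
    drift_targets: np.ndarray | None = None,
):
    """Solve the (ordinary or external-drift) kriging system for all targets."""
    tc = model.transform_coords(coords)
    tt = model.transform_coords(targets)
    n = len(values)
    d_ss = spatial.distance.cdist(tc, tc)
    d_st = spatial.distance.cdist(tc, tt)
    gam_ss = model.gamma(d_ss)
    np.fill_diagonal(gam_ss, 0.0)
    gam_st = model.gamma(d_st)
    # collapse exact co-location (numerically zero distance) to gamma = 0
    gam_st[d_st < 1e-9] = 0.0

    fcols = [np.ones(n)]
    frhs = [np.ones(len(targets))]
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        scale = np.ptp(drift)
        if scale > 1e-12 * max(1.0, np.abs(drift).max()):
            fcols.append(drift)
            frhs.append(np.asarray(drift_targets, dtype=float))
    F = np.column_stack(fcols)
    m = F.shape[1]
    A = np.zeros((n + m, n + m))
    A[:n, :n] = gam_ss
    A[:n, n:] = F
    A[n:, :n] = F.T
    b = np.vstack([gam_st, np.vstack(frhs)])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
    lam = sol[:n]
    mu = sol[n:]
    pred = lam.T @ values
    var = np.einsum("it,it->t", lam, gam_st) + np.einsum("it,it->t", mu, np.vstack(frhs))
    return pred, np.maximum(var, 0.0)


def ordinary_kriging(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
):
    """Ordinary kriging predictions and kriging variance at target locations.

    Exact interpolator at data points when the nugget is zero; the
    unbiasedness constraint makes the single-sample case return that value
    everywhere. For n > 500 samples each target uses its 32 nearest
    neighbours.
    """
    return external_drift_kriging(coords, values, model, None, targets, None)


def external_drift_kriging(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    auxiliary: np.ndarray | None,
    targets: np.ndarray,
    auxiliary_targets: np.ndarray | None,
):
    """Kriging with the mean modelled as affine in an auxiliary covariate.

    ``auxiliary`` holds the covariate at sample locations and
    ``auxiliary_targets`` at targets; a (near-)constant auxiliary degrades
    gracefully to ordinary kriging. Returns ``(predictions, variances)``.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(values) < 1:
        raise ValueError("need at least one sample")
    if auxiliary is not None:
        auxiliary = np.asarray(auxiliary, dtype=float)
        if auxiliary_targets is None:
            raise ValueError("auxiliary must be supplied at targets as well")
        auxiliary_targets = np.asarray(auxiliary_targets, dtype=float)
        bad = ~np.isfinite(auxiliary_targets)
        if bad.any():
            raise ValueError(
                f"auxiliary missing/non-finite at target cells {np.flatnonzero(bad).tolist()[:20]}"
            )
    coords, values, auxiliary = _dedup(coords, values, auxiliary)
    n = len(values)
    if n == 1:
        return np.full(len(targets), values[0]), np.full(len(targets), model.sill)

    if n <= GLOBAL_NEIGHBORHOOD_MAX:
        return _krige_system(coords, values, model, targets, auxiliary, auxiliary_targets)

    tree = spatial.cKDTree(model.transform_coords(coords))
    tt = model.transform_coords(targets)
    _, nbrs = tree.query(tt, k=min(N_NEIGHBORS, n))
    pred = np.empty(len(targets))
    var = np.empty(len(targets))
    for t in range(len(targets)):
        idx = np.atleast_1d(nbrs[t])
        p, v = _krige_system(
            coords[idx],
            values[idx],
            model,
            targets[t : t + 1],
            None if auxiliary is None else auxiliary[idx],
            None if auxiliary is None else auxiliary_targets[t : t + 1],
        )
        pred[t], var[t] = p[0], v[0]
    return pred, var


def regression_kriging(
    coords: np.ndarray,
    values: np.ndarray,
    covariates: np.ndarray,
    covariates_targets: np.ndarray,
    targets: np.ndarray,
    seed: int = 0,
    learner=None,
    lag_bins: np.ndarray | None = None,
):
    """Hybrid regression-kriging: tree-ensemble trend + ordinary kriging of
    the residuals; prediction = trend + kriged residual.

    The trend learner defaults to a random forest. The residual variogram is
    fitted internally (WLS, spherical/exponential). Constant covariates
    degenerate the learner to the sample mean (with a warning), which makes
    the procedure collapse to ordinary kriging.

    Returns ``(predictions, trend_at_targets, residual_variance)``.
    """
    from sklearn.ensemble import RandomForestRegressor

    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(values):
        X = X.T
    Xt = np.atleast_2d(np.asarray(covariates_targets, dtype=float))
    if Xt.shape[1] != X.shape[1]:
        Xt = Xt.T
    if np.all(np.ptp(X, axis=0) < 1e-12):
        warnings.warn("constant covariates: trend degenerates to the sample mean")
        trend = np.full(len(values), values.mean())
        trend_t = np.full(len(targets), values.mean())
    else:
        if learner is None:
            learner = RandomForestRegressor(
                n_estimators=200, min_samples_leaf=3, random_state=seed, n_jobs=1
            )
        learner.fit(X, values)
        trend = learner.predict(X)
        trend_t = learner.predict(Xt)

    resid = values - trend
    if lag_bins is None:
        d = spatial.distance.pdist(coords)
        lag_bins = np.linspace(1e-9, np.percentile(d, 60), 13)
    emp = empirical_variogram(coords, resid, lag_bins)
    try:
        model = fit_variogram(emp)
    except (ValueError, RuntimeError):
        warnings.warn("residual variogram unfittable; using pure-nugget residuals")
        return trend_t, trend_t, np.full(len(targets), resid.var())
    kr, kv = ordinary_kriging(coords, resid, model, targets)
    return trend_t + kr, trend_t, kv


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------

def censor_bounds(samples: pd.DataFrame, scenario: str) -> pd.Series:
    """Apply the lower/upper-bound substitution rules to censored samples.

    LB (minimalist): non-detect -> 0, detected-below-LOQ -> LOD.
    UB (maximalist): non-detect -> LOD, detected-below-LOQ -> LOQ.
    Quantified samples keep their measured value in both scenarios, so the
    UB series dominates the LB series elementwise.
    """
    scenario = scenario.upper()
    if scenario not in ("LB", "UB"):
        raise ValueError(f"scenario must be 'LB' or 'UB', got {scenario!r}")
    out = np.empty(len(samples))
    for k, r in enumerate(samples.itertuples()):
        if r.status == STATUS_QUANTIFIED:
            out[k] = r.value
        elif r.status == STATUS_BELOW_LOQ:
            out[k] = r.LOD if scenario == "LB" else r.LOQ
        elif r.status == STATUS_NON_DETECT:
            out[k] = 0.0 if scenario == "LB" else r.LOD
        else:
            raise ValueError(f"unknown censoring status {r.status!r}")
    return pd.Series(out, index=samples.index, name=f"value_{scenario.lower()}")


# ---------------------------------------------------------------------------
# Bootstrap EM for left-censored multivariate (log)normal data
# ---------------------------------------------------------------------------

def _trunc_upper_moments(m, s, b):
    """First two moments of N(m, s^2) truncated to (-inf, b), log-safe."""
    alpha = (b - m) / s
    log_phi = norm.logpdf(alpha)
    log_Phi = log_ndtr(alpha)
    h = np.exp(log_phi - log_Phi)
    e1 = m - s * h
    e2 = m**2 - 2 * m * s * h + s**2 * (1.0 - alpha * h)
    return e1, e2, log_Phi


@dataclass
class EMResult:
    mean: np.ndarray  # fitted mean of the (log-scale) MVN
    cov: np.ndarray
    loglik: float
    n_iter: int
    imputed: np.ndarray  # (n, p) data with censored entries replaced by E-step means
    draws: np.ndarray | None = None  # (n_boot, n, p) bootstrap imputation draws
    boot_means: np.ndarray | None = None  # (n_boot, p) bootstrap EM means


def _em_censored_mvn(obs: np.ndarray, bounds: np.ndarray, tol=1e-6, max_iter=500):
    """EM for a p-variate normal with left-censored entries.

    ``obs`` is (n, p) with NaN at censored entries; ``bounds`` holds the
    censoring threshold (same scale) wherever ``obs`` is NaN. The E-step is
    exact (univariate truncated-normal conditional moments) for rows with one
    censored coordinate; rows with several censored coordinates condition each
    censored coordinate on the observed ones only (documented approximation).
    The observed-data log-likelihood is asserted nondecreasing.
    """
    obs = np.asarray(obs, dtype=float)
    n, p = obs.shape
    cens = np.isnan(obs)
    if cens.all(axis=0).all():
        raise ValueError("all values censored for all substances: likelihood unidentified")
    if not cens.any():
        mu = obs.mean(axis=0)
        cov = np.cov(obs, rowvar=False, bias=True).reshape(p, p)
        ll = multivariate_normal.logpdf(obs, mu, cov, allow_singular=True).sum()
        return mu, cov, float(ll), 1, obs.copy()

    # init: censored at bound - log(2) (i.e. LOD/2 on the original scale)
    x0 = np.where(cens, np.asarray(bounds, dtype=float) - np.log(2.0), obs)
    mu = x0.mean(axis=0)
    cov = np.cov(x0, rowvar=False, bias=True).reshape(p, p)
    cov += 1e-8 * np.eye(p) * max(np.trace(cov) / p, 1e-12)

    prev_ll = -np.inf
    ex = x0.copy()
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for i in range(n):
            c = cens[i]
            if not c.any():
                xi = obs[i]
                sum_x += xi
                sum_xx += np.outer(xi, xi)
                ll += multivariate_normal.logpdf(xi, mu, cov, allow_singular=True)
                continue
            o = ~c
            xi = np.array(obs[i])
            exx = np.zeros((p, p))
            if o.any():
                So_inv = np.linalg.inv(cov[np.ix_(o, o)])
                resid = obs[i, o] - mu[o]
                cond_mean_c = mu[c] + cov[np.ix_(c, o)] @ So_inv @ resid
                cond_cov_c = cov[np.ix_(c, c)] - cov[np.ix_(c, o)] @ So_inv @ cov[np.ix_(o, c)]
                ll += multivariate_normal.logpdf(obs[i, o], mu[o], cov[np.ix_(o, o)],
                                                 allow_singular=True)
            else:
                cond_mean_c = mu[c].copy()
                cond_cov_c = cov[np.ix_(c, c)].copy()
            cidx = np.flatnonzero(c)
            if len(cidx) == 1:
                s = float(np.sqrt(max(cond_cov_c[0, 0], 1e-300)))
                e1, e2, logPhi = _trunc_upper_moments(
                    float(cond_mean_c[0]), s, float(bounds[i, cidx[0]])
                )
                xi[cidx[0]] = e1
                var_c = max(e2 - e1**2, 0.0)
                exx[cidx[0], cidx[0]] = var_c
                ll += logPhi
            else:
                # sequential approximation: each censored coordinate conditioned
                # on the observed coordinates only; cross-truncation ignored
                sd = np.sqrt(np.maximum(np.diag(cond_cov_c), 1e-300))
                for k, j in enumerate(cidx):
                    e1, e2, logPhi = _trunc_upper_moments(
                        float(cond_mean_c[k]), float(sd[k]), float(bounds[i, j])
                    )
                    xi[j] = e1
                    exx[j, j] = max(e2 - e1**2, 0.0)
                    ll += logPhi
            sum_x += xi
            sum_xx += np.outer(xi, xi) + exx
            ex[i] = xi
        mu_new = sum_x / n
        cov_new = sum_xx / n - np.outer(mu_new, mu_new)
        cov_new += 1e-10 * np.eye(p) * max(np.trace(cov_new) / p, 1e-12)
        # monotonicity of the observed-data log-likelihood (exact E-step rows)
        if ll < prev_ll - 1e-6 * (1.0 + abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        converged = np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (1.0 + abs(prev_ll))
        mu, cov, prev_ll = mu_new, cov_new, ll
        if converged:
            break
    return mu, cov, float(prev_ll), it, ex


def impute_censored_em(
    obs: np.ndarray | pd.DataFrame,
    bounds: np.ndarray | pd.DataFrame,
    n_boot: int = 1,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EMResult:
    """Bootstrap EM multiple imputation for left-censored multivariate normal
    (log-scale) samples.

    ``obs``: (n_stations, n_substances) log-values, NaN where censored;
    ``bounds``: log detection limits at the censored entries. The EM exploits
    the correlation between substances: censored coordinates are conditioned
    on the quantified ones. ``n_boot`` station-bootstrap replicates each refit
    the EM and draw imputations for the original censored entries from the
    conditional truncated normal, giving multiple imputed datasets.

    Deterministic for fixed ``(data, n_boot, seed)``.
    """
    if isinstance(obs, pd.DataFrame):
        obs = obs.to_numpy(dtype=float)
    if isinstance(bounds, pd.DataFrame):
        bounds = bounds.to_numpy(dtype=float)
    obs = np.asarray(obs, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    mu, cov, ll, it, ex = _em_censored_mvn(obs, bounds, tol=tol, max_iter=max_iter)

    n, p = obs.shape
    cens = np.isnan(obs)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, n, p))
    boot_means = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            bmu, bcov, _, _, _ = _em_censored_mvn(
                obs[idx], bounds[idx], tol=tol, max_iter=max_iter
            )
        except ValueError:
            bmu, bcov = mu, cov
        boot_means[b] = bmu
        # impute original censored entries from conditional truncated normal
        xi_all = obs.copy()
        for i in range(n):
            c = cens[i]
            if not c.any():
                continue
            o = ~c
            if o.any():
                So_inv = np.linalg.inv(bcov[np.ix_(o, o)])
                cm = bmu[c] + bcov[np.ix_(c, o)] @ So_inv @ (obs[i, o] - bmu[o])
                cc = bcov[np.ix_(c, c)] - bcov[np.ix_(c, o)] @ So_inv @ bcov[np.ix_(o, c)]
            else:
                cm, cc = bmu[c], bcov[np.ix_(c, c)]
            sd = np.sqrt(np.maximum(np.diag(np.atleast_2d(cc)), 1e-300))
            bnd = bounds[i, c]
            u = rng.random(len(sd))
            log_Phi = log_ndtr((bnd - cm) / sd)
            xi_all[i, c] = cm + sd * ndtri(np.exp(np.log(np.maximum(u, 1e-300)) + log_Phi))
        draws[b] = xi_all
    return EMResult(
        mean=mu, cov=cov, loglik=ll, n_iter=it, imputed=ex, draws=draws, boot_means=boot_means
    )


# ---------------------------------------------------------------------------
# Gaussian random field simulation (test utility + synthetic truth)
# ---------------------------------------------------------------------------

def simulate_gaussian_field(
    coords: np.ndarray,
    model: VariogramModel,
    seed: int,
    mean: float = 0.0,
) -> np.ndarray:
    """Unconditional Gaussian field at ``coords`` with the model's covariance
    C(h) = sill - gamma(h), by Cholesky factorisation (desk-scale n)."""
    coords = np.asarray(coords, dtype=float)
    tc = model.transform_coords(coords)
    d = spatial.distance.cdist(tc, tc)
    cov = model.sill - model.gamma(d)
    np.fill_diagonal(cov, model.sill)
    cov = cov + 1e-10 * model.sill * np.eye(len(coords))
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    return mean + L @ rng.standard_normal(len(coords))
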