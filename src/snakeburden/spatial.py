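"""Bayesian Poisson models for national rates and geostatistical risk mapping.

Two models, both with Poisson likelihood and log link:

* a national rate model for age- and sex-specific death rates (one parameter
  per age-sex cell, no global intercept, linear time trend centred on a
  reference year, person-years offsets);
* a geostatistical relative-risk model comparing observed unit deaths with
  the expectation under national rates:  y_i ~ Poisson(E_i * RR_i),
  log RR = x_i' beta + f(loc_i) + e_i, with a Matern (smoothness 1) Gaussian
  process f, an iid unit effect e, and weakly informative Gaussian priors on
  the regression coefficients.

Inference is empirical-Bayes MAP with a Laplace (Gaussian) approximation of
the posterior: field hyperparameters (spatial SD, range, unit-effect SD)
maximise the Laplace-approximate marginal likelihood, the latent field and
coefficients are the joint posterior mode, and credible intervals come from
the curvature at the mode.  An ensemble-MCMC mode (emcee) is available for
small problems as a cross-check of the approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.gaussian_process.kernels import Matern

from snakeburden.config import BANDS_UNDER_70


class ValidationError(ValueError):
    pass


class ShapeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# national age-sex rate model


@dataclass
class NationalRateModel:
    """Posterior summaries of the age-sex national rate model."""

    cells: list[tuple[str, str]]          # (age_band, sex)
    coef: np.ndarray                      # cell log rates then trend
    cov: np.ndarray
    ref_year: float
    rates: pd.DataFrame                   # per-cell rate/100k with CI at ref year

    @property
    def trend(self) -> float:
        return float(self.coef[-1])

    @property
    def trend_ci(self) -> tuple[float, float]:
        se = float(np.sqrt(self.cov[-1, -1]))
        return self.trend - 1.96 * se, self.trend + 1.96 * se

    def expected_deaths(self, exposure: pd.DataFrame) -> np.ndarray:
        """Expected deaths for rows of (age_band, sex, year, person_years)."""
        idx = {c: i for i, c in enumerate(self.cells)}
        keys = list(zip(exposure["age_band"], exposure["sex"]))
        missing = sorted({k for k in keys if k not in idx})
        if missing:
            raise ValidationError(f"age-sex cells absent from model: {missing[:5]}")
        cell_coef = self.coef[[idx[k] for k in keys]]
        eta = cell_coef + self.trend * (exposure["year"].to_numpy(float) - self.ref_year)
        return np.exp(eta) * exposure["person_years"].to_numpy(float)


def _map_poisson(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    prior_prec: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """MAP and posterior covariance of a Poisson GLM with Gaussian prior.

    Newton iterations with step halving on the penalized log likelihood;
    prior_prec is the (diagonal or full) prior precision matrix.
    """
    p = X.shape[1]
    beta = np.zeros(p)

    def obj(b):
        eta = X @ b + offset
        return float(y @ eta - np.exp(eta).sum() - 0.5 * b @ (prior_prec @ b))

    current = obj(beta)
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(eta)
        grad = X.T @ (y - mu) - prior_prec @ beta
        H = (X.T * mu) @ X + prior_prec
        step = np.linalg.solve(H, grad)
        t = 1.0
        while t > 1e-6:
            cand = beta + t * step
            val = obj(cand)
            if val >= current - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        if abs(val - current) < tol * (abs(current) + 1):
            current = val
            break
        current = val
    eta = X @ beta + offset
    H = (X.T * np.exp(eta)) @ X + prior_prec
    return beta, np.linalg.inv(H)


def fit_national_rates(
    data: pd.DataFrame,
    ref_year: float = 2010.0,
    prior_sd: float = 10.0,
) -> NationalRateModel:
    """Fit the Bayesian national Poisson rate model (ages 0-69).

    ``data`` has one row per (age_band, sex, year) -- or finer; rows are
    aggregated -- with ``deaths`` and ``person_years``.  Design: one
    indicator per age-sex cell (no intercept) plus a linear year trend
    centred on ``ref_year``; offset log person-years.  Cells with zero total
    exposure are dropped with a warning.
    """
    df = data[data["age_band"].isin(BANDS_UNDER_70)].copy()
    df = df.groupby(["age_band", "sex", "year"], as_index=False, observed=True).agg(
        deaths=("deaths", "sum"), person_years=("person_years", "sum")
    )
    exposure_by_cell = df.groupby(["age_band", "sex"], observed=True)["person_years"].sum()
    dead_cells = exposure_by_cell[exposure_by_cell <= 0].index.tolist()
    if dead_cells:
        warnings.warn(f"dropping age-sex cells with zero exposure: {dead_cells}")
        df = df.set_index(["age_band", "sex"]).drop(dead_cells).reset_index()
    if (df["person_years"] <= 0).any():
        df = df[df["person_years"] > 0]
    cells = sorted(set(zip(df["age_band"], df["sex"])))
    idx = {c: i for i, c in enumerate(cells)}
    n, p = len(df), len(cells) + 1
    X = np.zeros((n, p))
    for r, key in enumerate(zip(df["age_band"], df["sex"])):
        X[r, idx[key]] = 1.0
    X[:, -1] = df["year"].to_numpy(float) - ref_year
    y = df["deaths"].to_numpy(float)
    offset = np.log(df["person_years"].to_numpy(float))
    prior_prec = np.eye(p) / prior_sd**2
    coef, cov = _map_poisson(X, y, offset, prior_prec)
    se = np.sqrt(np.diag(cov)[:-1])
    rates = pd.DataFrame(
        {
            "age_band": [c[0] for c in cells],
            "sex": [c[1] for c in cells],
            "rate_per_100k": np.exp(coef[:-1]) * 1e5,
            "rate_lo": np.exp(coef[:-1] - 1.96 * se) * 1e5,
            "rate_hi": np.exp(coef[:-1] + 1.96 * se) * 1e5,
        }
    )
    return NationalRateModel(cells=cells, coef=coef, cov=cov, ref_year=ref_year, rates=rates)


# ---------------------------------------------------------------------------
# geostatistical relative-risk model


@dataclass
class GeoRRModel:
    """Fitted geostatistical relative-risk model (MAP + Laplace)."""

    unit_ids: np.ndarray
    coords: np.ndarray                    # (n, 2) lon, lat
    X: np.ndarray
    covariate_names: list[str]
    y: np.ndarray
    expected: np.ndarray
    beta: np.ndarray
    s: np.ndarray                         # combined spatial + iid latent, MAP
    joint_cov: np.ndarray                 # Laplace covariance of (beta, s)
    sigma_spatial: float
    spatial_range: float
    sigma_unit: float
    log_evidence: float
    cov_transform: dict[str, tuple[float, float]] = field(default_factory=dict)
    beta_prior_sd: float = 2.5
    nu: float = 1.0
    _kernel: Matern = field(repr=False, default=None)

    def hyperparam_ci(self, step: float = 0.15) -> pd.DataFrame:
        """Approximate 95% credible intervals for (spatial SD, range, unit SD).

        Finite-difference Hessian of the Laplace-approximate log marginal
        likelihood on the log-parameter scale, inverted to a Gaussian
        posterior; a flat direction (e.g. the unit SD shrunk to zero) gets an
        unbounded interval.
        """
        log_E = np.log(np.maximum(self.expected, 1e-12))
        lp = np.log([self.sigma_spatial, self.spatial_range, self.sigma_unit])

        def f(x):
            return -_neg_laplace_evidence(
                x, self.X, self.y, log_E, self.coords, self.beta_prior_sd, self.nu
            )[0]

        f0 = f(lp)
        H = np.zeros((3, 3))
        fp, fm = np.zeros(3), np.zeros(3)
        for i in range(3):
            ei = np.zeros(3)
            ei[i] = step
            fp[i], fm[i] = f(lp + ei), f(lp - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
        for i in range(3):
            for j in range(i + 1, 3):
                ei, ej = np.zeros(3), np.zeros(3)
                ei[i] = step
                ej[j] = step
                H[i, j] = H[j, i] = (f(lp + ei + ej) - fp[i] - fp[j] + f0) / step**2
        names = ["sigma_spatial", "spatial_range", "sigma_unit"]
        se = np.full(3, np.inf)
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            se = np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.inf)
        except np.linalg.LinAlgError:
            pass
        return pd.DataFrame(
            {
                "param": names,
                "estimate": np.exp(lp),
                "lo": np.exp(lp - 1.96 * se),
                "hi": np.exp(lp + 1.96 * se),
            }
        )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def _spatial_projection(self) -> tuple[np.ndarray, np.ndarray]:
        """A = Cov_sp (Cov_sp + tau^2 I)^-1 and conditional cov of f given s."""
        K = self.sigma_spatial**2 * self._kernel(self.coords)
        sigma = K + self.sigma_unit**2 * np.eye(self.n_units)
        A = np.linalg.solve(sigma, K).T
        cond = K - A @ K
        return A, cond

    def unit_rr(self) -> pd.DataFrame:
        """Posterior relative risk per unit, spatial part only.

        log RR_i = x_i' beta + f_i, excluding the iid unit effect (unit
        noise, not place); Gaussian posterior summaries on the log scale give
        the median and 95% credible interval of RR.
        """
        A, cond = self._spatial_projection()
        p = self.X.shape[1]
        J = np.hstack([self.X, A])           # maps (beta, s) -> eta_spatial
        mean = self.X @ self.beta + A @ self.s
        var = np.einsum("ij,jk,ik->i", J, self.joint_cov, J) + np.diag(cond)
        sd = np.sqrt(np.maximum(var, 0))
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "rr": np.exp(mean),
                "rr_lo": np.exp(mean - 1.96 * sd),
                "rr_hi": np.exp(mean + 1.96 * sd),
                "log_rr_sd": sd,
            }
        )


def _neg_laplace_evidence(
    log_params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    log_E: np.ndarray,
    coords: np.ndarray,
    beta_prior_sd: float,
    nu: float,
) -> tuple[float, dict]:
    """Negative Laplace-approximate log marginal likelihood at hyperparams."""
    sigma_sp, rng, tau = np.exp(log_params)
    n, p = X.shape
    kernel = Matern(length_scale=rng, nu=nu)
    sigma = sigma_sp**2 * kernel(coords) + tau**2 * np.eye(n)
    sigma[np.diag_indices_from(sigma)] += 1e-8
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e12, {}
    logdet_sigma = 2 * np.log(np.diag(L)).sum()
    Q = np.linalg.inv(sigma)

    # joint Newton over theta = (beta, s)
    P = np.zeros((p + n, p + n))
    P[:p, :p] = np.eye(p) / beta_prior_sd**2
    P[p:, p:] = Q
    theta = np.zeros(p + n)

    def parts(th):
        eta = X @ th[:p] + th[p:] + log_E
        mu = np.exp(eta)
        ll = float(y @ eta - mu.sum())
        pen = float(0.5 * th @ (P @ th))
        return eta, mu, ll - pen

    _, mu, current = parts(theta)
    for _ in range(60):
        eta = X @ theta[:p] + theta[p:] + log_E
        mu = np.exp(eta)
        resid = y - mu
        grad = np.concatenate([X.T @ resid, resid]) - P @ theta
        H = np.zeros((p + n, p + n))
        H[:p, :p] = (X.T * mu) @ X
        H[:p, p:] = X.T * mu
        H[p:, :p] = H[:p, p:].T
        H[p:, p:] = np.diag(mu)
        H += P
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return 1e12, {}
        t, val = 1.0, None
        while t > 1e-8:
            cand = theta + t * step
            _, _, val = parts(cand)
            if val >= current - 1e-12:
                break
            t /= 2
        theta = theta + t * step
        if abs(val - current) < 1e-8 * (abs(current) + 1):
            current = val
            break
        current = val

    eta = X @ theta[:p] + theta[p:] + log_E
    mu = np.exp(eta)
    H = np.zeros((p + n, p + n))
    H[:p, :p] = (X.T * mu) @ X
    H[:p, p:] = X.T * mu
    H[p:, :p] = H[:p, p:].T
    H[p:, p:] = np.diag(mu)
    H += P
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return 1e12, {}
    evidence = current - 0.5 * logdet_sigma - 0.5 * logdet_H
    info = {"theta": theta, "H": H, "kernel": kernel, "mu": mu}
    return -evidence, info


def fit_geostatistical_rr(
    unit_data: pd.DataFrame,
    covariates: list[str] | None = None,
    nu: float = 1.0,
    beta_prior_sd: float = 2.5,
    init: tuple[float, float, float] = (0.5, 1.5, 0.3),
    optimize_hyperparams: bool = True,
    max_opt_iter: int = 60,
) -> GeoRRModel:
    """Fit the geostatistical relative-risk model.

    ``unit_data`` has one row per sampling unit with columns ``unit_id``,
    ``lon``, ``lat``, ``deaths`` (observed, ages 0-69), ``expected``
    (expected deaths under the national rates) and any covariate columns.
    Default covariates, when present: rural flag, rural x female illiteracy,
    altitude (km) and long-term mean temperature.  Covariates are centred
    and (except flags) scaled before fitting; coefficients are reported on
    the transformed scale.
    """
    if (unit_data.loc[unit_data["deaths"] > 0, "expected"] <= 0).any():
        raise ValidationError("expected deaths must be positive where deaths observed")
    if covariates is None:
        covariates = [
            c
            for c in ("rural", "rural_illiteracy", "altitude_km", "temperature_c")
            if c in unit_data.columns
        ]
    bad = [
        c
        for c in covariates
        if not np.isfinite(unit_data[c].to_numpy(float)).all()
    ]
    if bad:
        first = unit_data.loc[
            ~np.isfinite(unit_data[bad[0]].to_numpy(float)), "unit_id"
        ].iloc[0]
        raise ValidationError(f"non-finite covariate {bad[0]} at unit {first}")

    n = len(unit_data)
    cols = [np.ones(n)]
    names = ["intercept"]
    transform: dict[str, tuple[float, float]] = {}
    for c in covariates:
        x = unit_data[c].to_numpy(float)
        center = float(x.mean())
        spread = float(x.std())
        is_flag = len(np.unique(x)) <= 2
        scale = spread if (spread > 1e-12 and not is_flag) else 1.0
        transform[c] = (center, scale)
        cols.append((x - center) / scale)
        names.append(c)
    X = np.column_stack(cols)
    y = unit_data["deaths"].to_numpy(float)
    expected = unit_data["expected"].to_numpy(float)
    log_E = np.log(np.maximum(expected, 1e-12))
    coords = unit_data[["lon", "lat"]].to_numpy(float)

    x0 = np.log(np.asarray(init, dtype=float))
    if optimize_hyperparams:
        res = minimize(
            lambda lp: _neg_laplace_evidence(lp, X, y, log_E, coords, beta_prior_sd, nu)[0],
            x0,
            method="Nelder-Mead",
            options={"maxfev": max_opt_iter, "xatol": 0.05, "fatol": 0.05},
        )
        lp_hat = res.x
    else:
        lp_hat = x0
    neg_ev, info = _neg_laplace_evidence(lp_hat, X, y, log_E, coords, beta_prior_sd, nu)
    if not info:
        raise RuntimeError("geostatistical fit failed at optimal hyperparameters")
    p = X.shape[1]
    theta = info["theta"]
    joint_cov = np.linalg.inv(info["H"])
    sigma_sp, rng, tau = np.exp(lp_hat)
    return GeoRRModel(
        unit_ids=unit_data["unit_id"].to_numpy(),
        coords=coords,
        X=X,
        covariate_names=names,
        y=y,
        expected=expected,
        beta=theta[:p],
        s=theta[p:],
        joint_cov=joint_cov,
        sigma_spatial=float(sigma_sp),
        spatial_range=float(rng),
        sigma_unit=float(tau),
        log_evidence=float(-neg_ev),
        cov_transform=transform,
        beta_prior_sd=beta_prior_sd,
        nu=nu,
        _kernel=info["kernel"],
    )


def sample_geostatistical_rr(
    model: GeoRRModel,
    n_steps: int = 1500,
    n_burn: int = 500,
    seed: int = 0,
    thin: int = 5,
) -> pd.DataFrame:
    """Full-posterior cross-check by ensemble MCMC (emcee) at the fitted
    hyperparameters; practical only for small unit counts.

    Returns per-unit posterior median RR (spatial part, as in
    :meth:`GeoRRModel.unit_rr`) from the samples.
    """
    import emcee

    n, p = model.n_units, model.X.shape[1]
    K = model.sigma_spatial**2 * model._kernel(model.coords)
    sigma = K + model.sigma_unit**2 * np.eye(n)
    sigma[np.diag_indices_from(sigma)] += 1e-8
    Q = np.linalg.inv(sigma)
    log_E = np.log(np.maximum(model.expected, 1e-12))
    prior_prec_beta = 1.0 / 2.5**2

    def log_post(th):
        beta, s = th[:p], th[p:]
        eta = model.X @ beta + s + log_E
        if np.any(eta > 50):
            return -np.inf
        mu = np.exp(eta)
        return float(
            model.y @ eta - mu.sum() - 0.5 * s @ (Q @ s) - 0.5 * prior_prec_beta * beta @ beta
        )

    ndim = p + n
    nwalkers = max(2 * ndim + 2, 64)
    rng = np.random.default_rng(seed)
    center = np.concatenate([model.beta, model.s])
    scales = np.sqrt(np.diag(model.joint_cov))
    p0 = center + 0.5 * scales * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
    sampler._random = np.random.RandomState(seed)
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, thin=thin, flat=True)
    A, _ = model._spatial_projection()
    etas = chain[:, :p] @ model.X.T + chain[:, p:] @ A.T
    med = np.exp(np.median(etas, axis=0))
    return pd.DataFrame({"unit_id": model.unit_ids, "rr": med})


# ---------------------------------------------------------------------------
# grid prediction and absolute risk


def predict_rr_grid(model: GeoRRModel, grid_covariates: pd.DataFrame) -> pd.DataFrame:
    """Posterior predictive relative risk on a grid.

    ``grid_covariates`` has one row per cell (row, col, lon, lat plus the
    model's covariate columns).  Prediction combines the covariate effect
    with the kriging projection of the spatial field; the iid unit effect is
    excluded.  Returns the grid table with rr (posterior median), rr_lo and
    rr_hi columns.
    """
    needed = [c for c in model.covariate_names if c != "intercept"]
    missing = [c for c in needed if c not in grid_covariates.columns]
    if missing:
        raise ShapeError(f"grid covariates missing columns: {missing}")
    m = len(grid_covariates)
    cols = [np.ones(m)]
    for c in needed:
        x = grid_covariates[c].to_numpy(float)
        center, scale = model.cov_transform[c]
        cols.append((x - center) / scale)
    Xg = np.column_stack(cols)
    pts = grid_covariates[["lon", "lat"]].to_numpy(float)

    n, p = model.n_units, model.X.shape[1]
    K = model.sigma_spatial**2 * model._kernel(model.coords)
    sigma = K + model.sigma_unit**2 * np.eye(n)
    sigma[np.diag_indices_from(sigma)] += 1e-8
    Kstar = model.sigma_spatial**2 * model._kernel(pts, model.coords)
    Astar = np.linalg.solve(sigma, Kstar.T).T           # (m, n)
    mean = Xg @ model.beta + Astar @ model.s
    J = np.hstack([Xg, Astar])
    var_param = np.einsum("ij,jk,ik->i", J, model.joint_cov, J)
    var_cond = model.sigma_spatial**2 - np.einsum("ij,ij->i", Astar, Kstar)
    sd = np.sqrt(np.maximum(var_param + var_cond, 0))
    out = grid_covariates.copy()
    out["rr"] = np.exp(mean)
    out["rr_lo"] = np.exp(mean - 1.96 * sd)
    out["rr_hi"] = np.exp(mean + 1.96 * sd)
    return out


def absolute_risk(
    surface: pd.DataFrame,
    national_risk_before_70_pct: float,
    thresholds: tuple[float, ...] = (0.6, 1.0),
) -> pd.DataFrame:
    """Absolute risk (%) of dying before 70: RR x national risk, cellwise.

    Adds ``abs_risk_pct`` (with lo/hi if rr_lo/rr_hi present) and one
    boolean exceedance column per threshold.
    """
    if not 0 < national_risk_before_70_pct < 100:
        raise ValidationError("national risk must be a percentage in (0, 100)")
    out = surface.copy()
    out["abs_risk_pct"] = out["rr"] * national_risk_before_70_pct
    for b in ("lo", "hi"):
        if f"rr_{b}" in out.columns:
            out[f"abs_risk_{b}"] = out[f"rr_{b}"] * national_risk_before_70_pct
    for t in thresholds:
        out[f"at_risk_ge_{t:g}pct"] = out["abs_risk_pct"] >= t
    return out


def population_at_risk(
    surface: pd.DataFrame,
    population: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.6, 1.0),
) -> pd.DataFrame:
    """People living in cells whose absolute risk meets each threshold.

    The population table must share the surface's grid geometry exactly
    (matching row/col/lon/lat); no silent resampling.
    """
    key = ["row", "col"]
    if len(surface) != len(population):
        raise ShapeError(
            f"surface has {len(surface)} cells, population {len(population)}; "
            "resample to a common grid first"
        )
    merged = surface.merge(population, on=key, how="inner", suffixes=("", "_pop"))
    if len(merged) != len(surface):
        raise ShapeError("surface and population grids do not share row/col indexing")
    for c in ("lon", "lat"):
        if f"{c}_pop" in merged and not np.allclose(merged[c], merged[f"{c}_pop"], atol=1e-6):
            raise ShapeError(f"surface and population grids disagree on {c}")
    total = merged["population"].sum()
    rows = []
    for t in thresholds:
        pop = merged.loc[merged["abs_risk_pct"] >= t, "population"].sum()
        rows.append(
            {
                "threshold_pct": t,
                "population": float(pop),
                "population_share": float(pop / total) if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
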