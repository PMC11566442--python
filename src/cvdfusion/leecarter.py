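"""Lee-Carter fitting and random-walk-with-drift projection.

The model for one (sex, obesity, education) stratum is

    log m_{x,t} = a_x + b_x * k_t + eps_{x,t}

over 8 five-year age groups x and T years t, identified by sum(b_x) = 1 and
sum(k_t) = 0, which makes a_x the time-mean of log m_{x,t}.  Estimation is
the classical SVD route: a_x is the row mean, (b_x, k_t) come from the
leading singular triple of the row-centered matrix rescaled so b sums to 1.
With that normalization the (b, k) -> (-b, -k) sign ambiguity is resolved
automatically and k's trend carries the sign of the age-averaged log-rate
trend.

The period index is forecast with a random walk with drift
(ARIMA(0,1,0)): k_t = k_{t-1} + d + e_t, e_t ~ (0, sigma^2).  Prediction
intervals include both innovation variance and drift-estimation variance:
Var(k_{T+h}) = h*sigma^2 + h^2*sigma^2/(T-1), the standard stochastic
mortality forecast variance; with T = 17 the drift term is non-negligible
at h = 10.  No second-stage re-estimation of k_t to match total deaths is
applied: the modelled quantity here is a conditional probability, not a
death count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_DEGENERATE_TOL = 1e-12


@dataclass
class LeeCarterFit:
    ax: np.ndarray          # (A,) age pattern: time-mean of log m
    bx: np.ndarray          # (A,) age sensitivities, sum 1
    kappa: np.ndarray       # (T,) period index, sum 0
    drift: float            # RWD drift d
    sigma: float            # RWD innovation sd
    explained_ratio: float  # share of centered variance in the rank-1 term
    degenerate: bool
    years: np.ndarray

    @property
    def fitted_log(self) -> np.ndarray:
        return self.ax[:, None] + self.bx[:, None] * self.kappa[None, :]


@dataclass
class ProjectionResult:
    years: np.ndarray        # horizon years
    log_central: np.ndarray  # (A, H)
    log_lower: np.ndarray
    log_upper: np.ndarray

    @property
    def central(self) -> np.ndarray:
        return np.exp(self.log_central)

    @property
    def lower(self) -> np.ndarray:
        return np.exp(self.log_lower)

    @property
    def upper(self) -> np.ndarray:
        return np.exp(self.log_upper)


def fit_rwd(kappa: np.ndarray) -> tuple[float, float]:
    """Drift and innovation sd of a random walk with drift.

    d is the mean first difference; sigma uses denominator T-2 (one degree
    of freedom lost to differencing, one to the drift).
    """
    kappa = np.asarray(kappa, dtype=float)
    T = kappa.size
    if T < 3:
        raise ValueError("random walk with drift needs at least 3 points")
    diffs = np.diff(kappa)
    d = float(diffs.mean())
    sigma = float(np.sqrt(((diffs - d) ** 2).sum() / (T - 2)))
    return d, sigma


def fit_lee_carter(log_m: np.ndarray, years) -> LeeCarterFit:
    """Fit the model to an (ages x years) matrix of log rates."""
    log_m = np.asarray(log_m, dtype=float)
    years = np.asarray(years)
    if log_m.ndim != 2:
        raise ValueError("log_m must be a 2-d (ages x years) matrix")
    A, T = log_m.shape
    if T < 3:
        raise ValueError("Lee-Carter needs at least 3 years")
    if T != years.size:
        raise ValueError("year labels do not match the matrix width")
    if not np.isfinite(log_m).all():
        raise ValueError("log_m contains non-finite entries")

    ax = log_m.mean(axis=1)
    centered = log_m - ax[:, None]
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((S**2).sum())
    scale = max(1.0, float(np.abs(log_m).max()))
    b_raw = U[:, 0]
    b_sum = float(b_raw.sum())
    degenerate = total_var <= (_DEGENERATE_TOL * scale) ** 2 or abs(b_sum) < 1e-10
    if degenerate:
        bx = np.full(A, 1.0 / A)
        kappa = np.zeros(T)
        drift, sigma = 0.0, 0.0
        explained = 1.0
    else:
        bx = b_raw / b_sum
        kappa = S[0] * Vt[0] * b_sum
        kappa = kappa - kappa.mean()  # numerical cleanup; exact zero sum
        drift, sigma = fit_rwd(kappa)
        explained = float(S[0] ** 2 / total_var)
    return LeeCarterFit(
        ax=ax,
        bx=bx,
        kappa=kappa,
        drift=drift,
        sigma=sigma,
        explained_ratio=explained,
        degenerate=degenerate,
        years=years,
    )


def project(
    fit: LeeCarterFit,
    horizon: int,
    level: float = 0.95,
    jumpoff: str = "fit",
    observed_last_log: np.ndarray | None = None,
) -> ProjectionResult:
    """Project the stratum ``horizon`` years past the jump-off year.

    Central forecast: k_{T+h} = k_T + h*d.  Forecast variance at horizon h
    is h*sigma^2 + h^2 * sigma^2/(T-1); log-scale bounds are the central
    value +/- z * sd * |b_x| per age.  ``jumpoff="fit"`` anchors at the
    fitted final-year value, ``"observed"`` shifts each age's path so it
    continues from the observed final-year log rate.
    """
    if horizon <= 0:
        raise ValueError("projection horizon must be positive")
    if jumpoff not in ("fit", "observed"):
        raise ValueError(f"unknown jump-off policy: {jumpoff!r}")
    T = fit.kappa.size
    h = np.arange(1, horizon + 1, dtype=float)
    kappa_f = fit.kappa[-1] + h * fit.drift
    var = h * fit.sigma**2 + (h**2) * fit.sigma**2 / (T - 1)
    z = stats.norm.ppf(0.5 + level / 2.0)
    sd = np.sqrt(var)

    central = fit.ax[:, None] + fit.bx[:, None] * kappa_f[None, :]
    if jumpoff == "observed":
        if observed_last_log is None:
            raise ValueError("observed jump-off requires observed_last_log")
        offset = np.asarray(observed_last_log) - fit.fitted_log[:, -1]
        central = central + offset[:, None]
    half = z * np.abs(fit.bx)[:, None] * sd[None, :]
    years = np.arange(int(fit.years[-1]) + 1, int(fit.years[-1]) + horizon + 1)
    return ProjectionResult(years, central, central - half, central + half)


def project_series(
    log_series: np.ndarray, years, horizon: int, level: float = 0.95
) -> pd.DataFrame:
    """Univariate RWD forecast of a single log-rate series (the alternative
    mode for an all-ages series): the series itself plays the role of the
    period index."""
    log_series = np.asarray(log_series, dtype=float)
    d, sigma = fit_rwd(log_series)
    T = log_series.size
    h = np.arange(1, horizon + 1, dtype=float)
    central = log_series[-1] + h * d
    sd = np.sqrt(h * sigma**2 + h**2 * sigma**2 / (T - 1))
    z = stats.norm.ppf(0.5 + level / 2.0)
    out_years = np.arange(int(np.asarray(years)[-1]) + 1, int(np.asarray(years)[-1]) + horizon + 1)
    return pd.DataFrame(
        {
            "year": out_years,
            "prob": np.exp(central),
            "lower": np.exp(central - z * sd),
            "upper": np.exp(central + z * sd),
        }
    )


def annualized_change(
    deaths: np.ndarray, exposure: np.ndarray, years, level: float = 0.95
) -> tuple[float, float, float]:
    """Annualized % rate of change over a period, with a Wald interval.

    Slope beta from a log-linear Poisson regression of death counts on
    calendar year with a log-exposure offset; reported as 100*(e^beta - 1).
    """
    deaths = np.asarray(deaths, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    years = np.asarray(years, dtype=float)
    if deaths.size < 2:
        raise ValueError("annualized change needs at least 2 years")
    if deaths.sum() <= 0:
        raise ValueError("annualized change undefined for all-zero counts")
    X = sm.add_constant(years - years.mean())
    model = sm.GLM(deaths, X, family=sm.families.Poisson(), offset=np.log(exposure))
    with warnings.catch_warnings():
        # exact log-linear inputs fit perfectly; the separation warning is benign
        warnings.simplefilter("ignore")
        res = model.fit()
    beta, se = res.params[1], res.bse[1]
    z = stats.norm.ppf(0.5 + level / 2.0)
    to_pct = lambda b: 100.0 * (np.exp(b) - 1.0)
    return to_pct(beta), to_pct(beta - z * se), to_pct(beta + z * se)


def fit_strata(surface: pd.DataFrame) -> dict[tuple, LeeCarterFit]:
    """Independent Lee-Carter fit per (sex, obesity, education) stratum of a
    conditional-surface table (12 strata for 2 sexes x 2 x 3).

    Cells with zero estimated probability (no deaths observed -- a
    desk-scale artifact national data never shows) are floored at half the
    stratum's smallest positive value before taking logs.
    """
    fits = {}
    for (sex, ob, edu), grp in surface.groupby(["sex", "obesity", "education"], observed=True):
        mat = grp.pivot_table(index="age_group", columns="year", values="prob", observed=True)
        mat = mat.sort_index(key=lambda idx: idx.astype(str).str.slice(0, 2).astype(int))
        years = np.asarray(sorted(mat.columns))
        vals = mat[years].to_numpy(dtype=float)
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError(f"stratum ({sex}, {ob}, {edu}) has no positive probabilities")
        vals = np.where(vals > 0, vals, 0.5 * positive.min())
        fits[(sex, int(ob), edu)] = fit_lee_carter(np.log(vals), years)
    return fits


def aggregate_projection(
    proj: ProjectionResult, weights: np.ndarray
) -> pd.DataFrame:
    """Exposure-weighted all-age aggregate of a per-age projection.

    Ages within a stratum share the single period shock b_x * k, so their
    forecasts are comonotone (for b_x of one sign) and the aggregate
    quantile is the weighted mean of per-age quantiles.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return pd.DataFrame(
        {
            "year": proj.years,
            "prob": w @ proj.central,
            "lower": w @ proj.lower,
            "upper": w @ proj.upper,
        }
    )
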