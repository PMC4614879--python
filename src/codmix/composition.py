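"""State-space model of catch composition through time.

Counts of assigned individuals at each sampling year are multinomial
observations of a 4-category probability vector that follows a latent
3-dimensional Gaussian random walk mapped to the simplex by the additive
logistic transform. The innovation SD is estimated by maximizing a
Laplace-approximated marginal likelihood; credible bands come from a
Gaussian approximation around the posterior mode. Fitted proportions are
finally multiplied by total stock biomass to apportion it by population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from codmix.genio import CatchCountTable

logger = logging.getLogger("codmix")


class FitError(RuntimeError):
    """Raised when the state-space optimizer fails to converge."""


@dataclass
class CompositionSeries:
    """Fitted latent path, simplex proportions and uncertainty."""

    times: np.ndarray  # decimal years, strictly increasing
    alpha_path: np.ndarray  # (n, 3) latent MAP states
    sigma: float  # innovation SD per sqrt(year)
    p_path: np.ndarray  # (n, 4) simplex vectors
    bands: dict = field(default_factory=dict)  # {"lo": (n,4), "hi": (n,4), "level": float}
    cov: np.ndarray | None = None  # (3n, 3n) curvature-based covariance
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        sums = self.p_path.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each p_t must sum to 1")


@dataclass
class BiomassApportionment:
    years: np.ndarray
    total_biomass: np.ndarray
    per_population: np.ndarray  # (n_years, K)
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        recon = self.per_population.sum(axis=1)
        if not np.allclose(recon, self.total_biomass, rtol=1e-6):
            raise ValueError("per-population biomasses must sum to the total")

    def to_frame(self) -> pd.DataFrame:
        pops = self.populations or [f"pop{k+1}" for k in range(self.per_population.shape[1])]
        rows = []
        for i, y in enumerate(self.years):
            for k, p in enumerate(pops):
                rows.append({"year": y, "population": p, "biomass": self.per_population[i, k]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simplex transform
# ---------------------------------------------------------------------------


def simplex_transform(alpha: np.ndarray) -> np.ndarray:
    """Additive-logistic map from R^3 (last axis) to the 4-simplex.

    p_k = exp(α_k) / (1 + Σ exp(α_j)) for k = 1..3, p_4 the remainder;
    computed with max-subtraction so large |α| cannot overflow.
    """
    alpha = np.asarray(alpha, dtype=float)
    ext = np.concatenate([alpha, np.zeros(alpha.shape[:-1] + (1,))], axis=-1)
    ext = ext - ext.max(axis=-1, keepdims=True)
    w = np.exp(ext)
    return w / w.sum(axis=-1, keepdims=True)


def inverse_transform(p: np.ndarray) -> np.ndarray:
    """Inverse of :func:`simplex_transform` on interior points."""
    p = np.asarray(p, dtype=float)
    return np.log(p[..., :3]) - np.log(p[..., 3:4])


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------


def _multinomial_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    # constant (multinomial coefficient) omitted: it does not depend on alpha
    with np.errstate(divide="ignore"):
        terms = np.where(counts > 0, counts * np.log(p), 0.0)
    return float(terms.sum())


def joint_loglik(
    counts: np.ndarray,
    alpha_path: np.ndarray,
    sigma: float,
    times: np.ndarray,
    dt_scaling: bool = True,
) -> float:
    """Joint log-likelihood of counts and latent path.

    ``counts`` is (n, 4) aggregated per time; the random-walk increments
    are N(0, σ²Δt) per dimension (Δt in years) when ``dt_scaling``, else
    N(0, σ²). The initial state carries a flat (improper) prior.
    """
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times, dtype=float)
    alpha_path = np.asarray(alpha_path, dtype=float).reshape(len(times), 3)
    if len(times) > 1 and not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    p = simplex_transform(alpha_path)
    ll = _multinomial_loglik(counts, p)
    if len(times) > 1:
        dt = np.diff(times) if dt_scaling else np.ones(len(times) - 1)
        inc = np.diff(alpha_path, axis=0)
        var = sigma**2 * dt[:, None]
        ll += float(
            (-0.5 * np.log(2 * np.pi * var) - 0.5 * inc**2 / var).sum()
        )
    return ll


def _neg_joint_and_grad(
    flat_alpha: np.ndarray,
    counts: np.ndarray,
    N: np.ndarray,
    sigma: float,
    dt: np.ndarray,
) -> tuple[float, np.ndarray]:
    n = len(N)
    alpha = flat_alpha.reshape(n, 3)
    p = simplex_transform(alpha)
    with np.errstate(divide="ignore"):
        obs = np.where(counts > 0, counts * np.log(p), 0.0).sum()
    grad = counts[:, :3] - N[:, None] * p[:, :3]
    rw = 0.0
    if n > 1:
        inc = np.diff(alpha, axis=0)
        var = sigma**2 * dt[:, None]
        rw = (-0.5 * np.log(2 * np.pi * var) - 0.5 * inc**2 / var).sum()
        g_rw = np.zeros_like(alpha)
        z = inc / var
        g_rw[:-1] += z
        g_rw[1:] -= z
        grad = grad + g_rw
    return -(obs + rw), -grad.ravel()


def _neg_hessian(
    alpha: np.ndarray, N: np.ndarray, sigma: float, dt: np.ndarray
) -> np.ndarray:
    """Dense negative Hessian (precision) of the joint log-likelihood."""
    n = len(N)
    H = np.zeros((3 * n, 3 * n))
    p = simplex_transform(alpha)
    for i in range(n):
        q = p[i, :3]
        block = N[i] * (np.diag(q) - np.outer(q, q))
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
    if n > 1:
        for i in range(n - 1):
            prec = 1.0 / (sigma**2 * dt[i])
            for k in range(3):
                a, b = 3 * i + k, 3 * (i + 1) + k
                H[a, a] += prec
                H[b, b] += prec
                H[a, b] -= prec
                H[b, a] -= prec
    return H


def _map_path(
    counts: np.ndarray,
    times: np.ndarray,
    sigma: float,
    dt_scaling: bool,
    start: np.ndarray | None = None,
) -> np.ndarray:
    n = len(times)
    N = counts.sum(axis=1).astype(float)
    dt = (np.diff(times) if dt_scaling else np.ones(n - 1)) if n > 1 else np.array([])
    x0 = np.zeros(3 * n) if start is None else start.ravel().copy()
    res = minimize(
        _neg_joint_and_grad,
        x0,
        args=(counts, N, sigma, dt),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        res2 = minimize(
            _neg_joint_and_grad,
            res.x,
            args=(counts, N, sigma, dt),
            jac=True,
            method="BFGS",
            options={"maxiter": 2000, "gtol": 1e-8},
        )
        if np.linalg.norm(res2.jac) < np.linalg.norm(res.jac):
            res = res2
        if np.linalg.norm(res.jac) > 1e-3:
            raise FitError(f"inner optimizer did not converge: {res.message}")
    return res.x.reshape(n, 3)


def laplace_marginal_loglik(
    counts: np.ndarray,
    times: np.ndarray,
    sigma: float,
    dt_scaling: bool = True,
    start: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Laplace approximation to the marginal log-likelihood at ``sigma``.

    Returns (marginal loglik, MAP alpha path).
    """
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(times)
    alpha = _map_path(counts, times, sigma, dt_scaling, start)
    N = counts.sum(axis=1).astype(float)
    dt = (np.diff(times) if dt_scaling else np.ones(n - 1)) if n > 1 else np.array([])
    joint = joint_loglik(counts, alpha, sigma, times, dt_scaling)
    H = _neg_hessian(alpha, N, sigma, dt)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise FitError("negative Hessian not positive definite at the mode")
    ml = joint + 0.5 * 3 * n * np.log(2 * np.pi) - 0.5 * logdet
    return ml, alpha


def fit_state_space(
    counts: CatchCountTable | np.ndarray,
    times: np.ndarray | None = None,
    sigma: float | None = None,
    seed: int | None = None,
    dt_scaling: bool = True,
    n_band_draws: int = 4000,
    band_level: float = 0.90,
) -> CompositionSeries:
    """Fit the compositional state-space model.

    ``sigma=None`` estimates the innovation SD by maximizing the
    Laplace-approximated marginal likelihood over log σ; a float fixes it.
    Credible bands are Monte-Carlo quantiles of ``n_band_draws`` seeded
    draws from the Gaussian approximation at the mode, mapped through the
    simplex transform.
    """
    populations = None
    if isinstance(counts, CatchCountTable):
        pooled = counts.aggregate_by_time()
        populations = pooled.populations
        times = pooled.times
        counts = pooled.counts
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(times)
    if counts.shape[0] != n:
        raise ValueError("counts rows must align with times")
    if (counts.sum(axis=1) < 1).any():
        raise ValueError("each time needs at least one assigned individual")
    if sigma is None:
        if n < 2:
            raise ValueError("sigma estimation needs >= 2 time points")
        state: dict = {"alpha": None}

        def neg_ml(log_sigma: float) -> float:
            ml, alpha = laplace_marginal_loglik(
                counts, times, float(np.exp(log_sigma)), dt_scaling, state["alpha"]
            )
            state["alpha"] = alpha
            return -ml

        res = minimize_scalar(
            neg_ml, bounds=(np.log(1e-3), np.log(10.0)), method="bounded",
            options={"xatol": 1e-4},
        )
        if not res.success:
            raise FitError(f"outer sigma optimizer failed: {res}")
        sigma_hat = float(np.exp(res.x))
    else:
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        sigma_hat = float(sigma)
    _, alpha = laplace_marginal_loglik(counts, times, sigma_hat, dt_scaling)
    N = counts.sum(axis=1).astype(float)
    dt = (np.diff(times) if dt_scaling else np.ones(n - 1)) if n > 1 else np.array([])
    H = _neg_hessian(alpha, N, sigma_hat, dt)
    cov = np.linalg.inv(H)
    p_path = simplex_transform(alpha)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(3 * n))
    z = rng.standard_normal((n_band_draws, 3 * n))
    draws = alpha.ravel()[None, :] + z @ L.T
    p_draws = simplex_transform(draws.reshape(n_band_draws, n, 3))
    lo_q, hi_q = (1 - band_level) / 2, 1 - (1 - band_level) / 2
    lo = np.quantile(p_draws, lo_q, axis=0)
    hi = np.quantile(p_draws, hi_q, axis=0)
    # bands must contain the point estimate
    lo = np.minimum(lo, p_path)
    hi = np.maximum(hi, p_path)
    return CompositionSeries(
        times=times,
        alpha_path=alpha,
        sigma=sigma_hat,
        p_path=p_path,
        bands={"lo": lo, "hi": hi, "level": band_level},
        cov=cov,
        populations=populations,
    )


def interpolate_alpha(series: CompositionSeries, years: np.ndarray) -> np.ndarray:
    """Conditional mode of the latent walk at arbitrary years.

    Between observations the Brownian-bridge mode is the time-linear
    interpolation of the fitted states; beyond the ends the random-walk
    prediction is flat. Requests more than 5 years outside the observed
    span are refused.
    """
    years = np.asarray(years, dtype=float)
    t0, t1 = series.times[0], series.times[-1]
    if (years < t0 - 5).any() or (years > t1 + 5).any():
        raise ValueError("requested year more than 5 years outside the fitted span")
    out = np.empty((len(years), 3))
    for k in range(3):
        out[:, k] = np.interp(years, series.times, series.alpha_path[:, k])
    return out


def apportion_biomass(
    series: CompositionSeries, biomass: pd.Series
) -> BiomassApportionment:
    """Split total biomass by population using interpolated proportions."""
    years = np.asarray(biomass.index, dtype=float)
    alpha = interpolate_alpha(series, years)
    p = simplex_transform(alpha)
    total = biomass.to_numpy(dtype=float)
    per_pop = p * total[:, None]
    return BiomassApportionment(
        years=years,
        total_biomass=total,
        per_population=per_pop,
        populations=series.populations,
    )


def series_to_frame(series: CompositionSeries) -> pd.DataFrame:
    """Tidy (year, population, p, lo, hi) layout."""
    pops = series.populations or [f"pop{k+1}" for k in range(4)]
    rows = []
    for i, t in enumerate(series.times):
        for k, pop in enumerate(pops):
            rows.append(
                {
                    "year": t,
                    "population": pop,
                    "p": series.p_path[i, k],
                    "lo": series.bands["lo"][i, k],
                    "hi": series.bands["hi"][i, k],
                }
            )
    return pd.DataFrame(rows)
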