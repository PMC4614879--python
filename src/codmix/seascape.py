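"""Seascape connectivity and regime-shift detection.

Yearly suitability grids become cost surfaces (cost = 1 − suitability with
a floor), accumulated-cost distances from an entry cell are computed by
Dijkstra on the 8-neighbour raster graph, stratum proportions of the two
major populations are regressed on those distances with a binomial GLM,
and yearly mean log suitability is segmented by the sequential t-test
regime detection algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra
from scipy.stats import t as t_dist

from codmix.genio import GridSeries

logger = logging.getLogger("codmix")


@dataclass
class CostSurface:
    """Per-cell traversal costs on sea cells; land impassable."""

    costs: np.ndarray  # (nrows, ncols), NaN on land
    mask: np.ndarray  # bool, True on sea
    cell_size_km: float

    def __post_init__(self) -> None:
        sea = self.costs[self.mask]
        if not np.isfinite(sea).all() or (sea < 0).any():
            raise ValueError("sea-cell costs must be finite and >= 0")


@dataclass
class RegimeSegmentation:
    years: np.ndarray
    change_points: list[int]  # years at which new regimes start
    regime_means: list[float]
    rsi: dict  # candidate year -> regime shift index
    cutoff_years: int
    significance: float

    def segments(self) -> list[tuple[int, int]]:
        bounds = [int(self.years[0])] + list(self.change_points) + [int(self.years[-1]) + 1]
        return [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# cost surfaces and distances
# ---------------------------------------------------------------------------


def cost_surface(
    suitability: np.ndarray,
    mask: np.ndarray,
    cell_size_km: float = 50.0,
    epsilon: float = 0.01,
) -> CostSurface:
    """cost = max(1 − suitability, ε) on sea cells; land excluded."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all-land grid")
    s = np.asarray(suitability, dtype=float)
    if ((s[mask] < 0) | (s[mask] > 1)).any():
        raise ValueError("suitability must lie in [0, 1] on sea cells")
    costs = np.full(mask.shape, np.nan)
    costs[mask] = np.maximum(1.0 - s[mask], epsilon)
    return CostSurface(costs=costs, mask=mask, cell_size_km=cell_size_km)


_NEIGHBOURS = [
    (-1, -1, np.sqrt(2)), (-1, 0, 1.0), (-1, 1, np.sqrt(2)),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, np.sqrt(2)), (1, 0, 1.0), (1, 1, np.sqrt(2)),
]


def _grid_graph(surface: CostSurface):
    """Sparse 8-neighbour graph; edge = mean endpoint cost x step length."""
    nrows, ncols = surface.mask.shape
    idx = -np.ones((nrows, ncols), dtype=int)
    sea = np.argwhere(surface.mask)
    idx[surface.mask] = np.arange(len(sea))
    rows, cols, data = [], [], []
    for dr, dc, step in _NEIGHBOURS:
        r, c = sea[:, 0], sea[:, 1]
        r2, c2 = r + dr, c + dc
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
        r, c, r2, c2 = r[ok], c[ok], r2[ok], c2[ok]
        ok2 = surface.mask[r2, c2]
        r, c, r2, c2 = r[ok2], c[ok2], r2[ok2], c2[ok2]
        w = (
            0.5
            * (surface.costs[r, c] + surface.costs[r2, c2])
            * step
            * surface.cell_size_km
        )
        rows.append(idx[r, c])
        cols.append(idx[r2, c2])
        data.append(w)
    n = len(sea)
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return graph, idx


def least_cost_distance(
    surface: CostSurface,
    source: tuple[int, int],
    targets: list[tuple[int, int]] | None = None,
) -> np.ndarray | dict:
    """Accumulated least cost from ``source`` to targets (or every sea cell).

    Unreachable targets come back as +inf. Returns a full (nrows, ncols)
    array of accumulated costs when ``targets`` is None, otherwise a dict
    target -> cost.
    """
    if not surface.mask[source]:
        raise ValueError(f"source cell {source} is on land")
    graph, idx = _grid_graph(surface)
    dist = _sp_dijkstra(graph, directed=False, indices=idx[source])
    if targets is None:
        out = np.full(surface.mask.shape, np.inf)
        out[surface.mask] = dist
        out[~surface.mask] = np.nan
        return out
    res = {}
    for t in targets:
        if not surface.mask[t]:
            raise ValueError(f"target cell {t} is on land")
        res[t] = float(dist[idx[t]])
    return res


def shortest_sea_distance(
    mask: np.ndarray,
    source: tuple[int, int],
    targets: list[tuple[int, int]] | None = None,
    cell_size_km: float = 50.0,
):
    """Geodesic-through-sea distance: Dijkstra with unit cell cost."""
    mask = np.asarray(mask, dtype=bool)
    costs = np.where(mask, 1.0, np.nan)
    surface = CostSurface(costs=costs, mask=mask, cell_size_km=cell_size_km)
    return least_cost_distance(surface, source, targets)


def stratum_distances(
    dist_grid: np.ndarray, strata: dict[str, list[tuple[int, int]]]
) -> dict[str, float]:
    """Mean accumulated distance over each stratum's sea cells."""
    out = {}
    for name, cells in strata.items():
        vals = np.array([dist_grid[c] for c in cells], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if len(vals) else np.inf
    return out


# ---------------------------------------------------------------------------
# binomial GLM of proportion vs distance
# ---------------------------------------------------------------------------


@dataclass
class GlmResult:
    slope: float
    intercept: float
    p_value: float
    r2: float  # deviance-based coefficient of determination
    separated: bool = False


def proportion_distance_glm(
    successes: np.ndarray, totals: np.ndarray, distances: np.ndarray
) -> GlmResult:
    """Logistic regression of a two-population proportion on distance.

    ``successes`` counts the focal population out of ``totals`` per
    stratum. R² is 1 − residual deviance / null deviance; the p-value is
    the Wald z test on the slope. Complete separation triggers a weakly
    penalized fallback fit, flagged in the result.
    """
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if (totals <= 0).any():
        raise ValueError("every stratum needs a nonzero total")
    if len(distances) < 3:
        raise ValueError("need >= 3 strata")
    endog = np.column_stack([successes, totals - successes])
    exog = sm.add_constant(distances)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit()
            if (
                np.abs(fit.params).max() > 1e3
                or not np.isfinite(fit.bse).all()
                or fit.bse.max() > 1e3
            ):
                raise ValueError("separation suspected")
            slope, intercept = fit.params[1], fit.params[0]
            p_value = fit.pvalues[1]
            r2 = 1.0 - fit.deviance / fit.null_deviance
        except Exception:
            separated = True
            logger.warning("complete separation; penalized fallback fit used")
            fit = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
            slope, intercept = fit.params[1], fit.params[0]
            mu = model.predict(fit.params, exog)
            dev = model.family.deviance(model.endog, mu, freq_weights=model.freq_weights)
            null_mu = np.full_like(mu, successes.sum() / totals.sum())
            null_dev = model.family.deviance(
                model.endog, null_mu, freq_weights=model.freq_weights
            )
            r2 = 1.0 - dev / null_dev
            p_value = np.nan
    return GlmResult(
        slope=float(slope),
        intercept=float(intercept),
        p_value=float(p_value),
        r2=float(np.clip(r2, 0.0, 1.0)),
        separated=separated,
    )


def compare_distance_models(
    successes: np.ndarray,
    totals: np.ndarray,
    model_distances: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Fit the proportion-vs-distance GLM per predictor; rank by R²."""
    rows = []
    for name, d in model_distances.items():
        res = proportion_distance_glm(successes, totals, d)
        rows.append(
            {
                "model": name,
                "r2": res.r2,
                "slope": res.slope,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows).sort_values("r2", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# regime shift detection (sequential t-test)
# ---------------------------------------------------------------------------


def regime_shift_detect(
    years: np.ndarray,
    values: np.ndarray,
    cutoff_years: int = 5,
    significance: float = 0.1,
) -> RegimeSegmentation:
    """Sequential t-test regime detection on an annual series.

    A new regime is proposed when a value leaves the current regime mean by
    more than diff = t_{1−sig/2, 2l−2} · sqrt(2 σ̄_l² / l), with σ̄_l² the
    average variance over consecutive l-year windows; the candidate is
    confirmed only if the cumulative regime-shift index over the following
    l years stays positive. Regime means are the plain segment means of
    the confirmed partition.
    """
    years = np.asarray(years, dtype=int)
    x = np.asarray(values, dtype=float)
    l = int(cutoff_years)
    n = len(x)
    if n < 2 * l:
        raise ValueError(f"series length {n} shorter than 2 x cutoff {l}")
    win_vars = np.array([x[i : i + l].var(ddof=1) for i in range(n - l + 1)])
    sigma2 = float(win_vars.mean())
    t_crit = t_dist.ppf(1 - significance / 2, df=2 * l - 2)
    diff = t_crit * np.sqrt(2.0 * sigma2 / l)
    regime_start = 0
    change_points: list[int] = []
    rsi: dict[int, float] = {}
    i = l
    while i < n:
        mean = x[regime_start:i].mean()
        if abs(x[i] - mean) > diff:
            sign = 1.0 if x[i] > mean else -1.0
            level = mean + sign * diff
            csum = 0.0
            confirmed = True
            span = min(l, n - i)
            for j in range(i, i + span):
                csum += sign * (x[j] - level) / (l * np.sqrt(sigma2))
                if csum < 0:
                    confirmed = False
                    break
            rsi[int(years[i])] = csum if confirmed else 0.0
            if confirmed:
                change_points.append(int(years[i]))
                regime_start = i
        i += 1
    bounds = [0] + [int(np.where(years == cp)[0][0]) for cp in change_points] + [n]
    regime_means = [
        float(x[bounds[k] : bounds[k + 1]].mean()) for k in range(len(bounds) - 1)
    ]
    return RegimeSegmentation(
        years=years,
        change_points=change_points,
        regime_means=regime_means,
        rsi=rsi,
        cutoff_years=l,
        significance=significance,
    )


def mean_suitability_series(
    suitability: GridSeries, transform: str = "log", floor: float = 1e-6
) -> pd.Series:
    """Yearly mean suitability over sea cells, optionally log-transformed."""
    if not suitability.mask.any():
        raise ValueError("empty sea mask")
    vals = []
    for year in suitability.years:
        m = float(np.nanmean(suitability.sea_values(year)))
        vals.append(np.log(max(m, floor)) if transform == "log" else m)
    return pd.Series(vals, index=pd.Index(suitability.years, name="year"))
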