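"""Ensemble habitat-suitability modelling and yearly hindcasting.

Four techniques — quadratic logistic regression, a natural-cubic-spline
additive logistic model, gradient-boosted trees and a random forest — are
fitted on presence/absence records with absences down-weighted to match
the presences, evaluated on repeated random 80/20 splits with AUC, refit
on all records and averaged to hindcast suitability onto yearly grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from codmix.genio import GridSeries

logger = logging.getLogger("codmix")

TECHNIQUES = ("glm", "gam", "gbm", "rf")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "glm": {"C": 100.0},
    "gam": {"df": 4, "C": 100.0},
    "gbm": {
        "n_estimators": 1000,
        "max_depth": 3,
        "learning_rate": 0.01,
        "subsample": 0.5,
    },
    "rf": {"n_estimators": 500},
}


# ---------------------------------------------------------------------------
# technique wrappers
# ---------------------------------------------------------------------------


def _quadratic_features(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, X**2])


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    With K knots this yields K-1 columns: x itself plus K-2 truncated
    cubic differences.
    """
    K = len(knots)
    xiK, xiK1 = knots[-1], knots[-2]

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - xiK, 0, None) ** 3
        return num / (xiK - knots[k])

    dK1 = d(K - 2)
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols)


class _GlmTechnique:
    """Logistic regression with linear + quadratic terms."""

    def __init__(self, C: float = 100.0):
        self.C = C

    def fit(self, X, y, w):
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Z = _quadratic_features((X - self._mu) / self._sd)
        self._clf = LogisticRegression(C=self.C, max_iter=1000)
        self._clf.fit(Z, y, sample_weight=w)
        return self

    def predict(self, X):
        Z = _quadratic_features((X - self._mu) / self._sd)
        return self._clf.predict_proba(Z)[:, 1]


class _GamTechnique:
    """Additive logistic model on natural cubic spline bases."""

    def __init__(self, df: int = 4, C: float = 100.0):
        self.df = df
        self.C = C

    def fit(self, X, y, w):
        self._knots = []
        cols = []
        for j in range(X.shape[1]):
            qs = np.linspace(0.02, 0.98, self.df + 1)
            knots = np.unique(np.quantile(X[:, j], qs))
            if len(knots) < 3:  # nearly-constant predictor: keep linear term
                knots = np.array([X[:, j].min() - 1.0, X[:, j].mean(), X[:, j].max() + 1.0])
            self._knots.append(knots)
            cols.append(_natural_spline_basis(X[:, j], knots))
        Z = np.hstack(cols)
        self._mu = Z.mean(axis=0)
        self._sd = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        self._clf = LogisticRegression(C=self.C, max_iter=2000)
        self._clf.fit((Z - self._mu) / self._sd, y, sample_weight=w)
        return self

    def predict(self, X):
        cols = [
            _natural_spline_basis(X[:, j], self._knots[j]) for j in range(X.shape[1])
        ]
        Z = np.hstack(cols)
        return self._clf.predict_proba((Z - self._mu) / self._sd)[:, 1]


class _GbmTechnique:
    def __init__(self, seed: int = 0, **params):
        self.params = params
        self.seed = seed

    def fit(self, X, y, w):
        self._clf = GradientBoostingClassifier(random_state=self.seed, **self.params)
        self._clf.fit(X, y, sample_weight=w)
        return self

    def predict(self, X):
        return self._clf.predict_proba(X)[:, 1]


class _RfTechnique:
    def __init__(self, seed: int = 0, **params):
        self.params = params
        self.seed = seed

    def fit(self, X, y, w):
        self._clf = RandomForestClassifier(random_state=self.seed, **self.params)
        self._clf.fit(X, y, sample_weight=w)
        return self

    def predict(self, X):
        return self._clf.predict_proba(X)[:, 1]


def _make_technique(name: str, seed: int, hyperparams: dict):
    params = dict(DEFAULT_HYPERPARAMS[name])
    params.update(hyperparams.get(name, {}))
    if name == "glm":
        return _GlmTechnique(**params)
    if name == "gam":
        return _GamTechnique(**params)
    if name == "gbm":
        return _GbmTechnique(seed=seed, **params)
    if name == "rf":
        return _RfTechnique(seed=seed, **params)
    raise ValueError(f"unknown technique '{name}'")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class SDMEnsemble:
    """Four fitted techniques with their split-evaluation AUC table."""

    predictors: list[str]
    models: dict  # technique name -> fitted wrapper
    auc_table: pd.DataFrame  # columns: technique, repetition, auc
    weights: np.ndarray
    train_range: dict = field(default_factory=dict)  # predictor -> (min, max)

    def predict(self, X: np.ndarray, technique: str | None = None) -> np.ndarray:
        """Ensemble mean (or one member's) suitability, clipped to [0, 1]."""
        X = np.asarray(X, dtype=float)
        if technique is not None:
            return np.clip(self.models[technique].predict(X), 0.0, 1.0)
        preds = [self.models[t].predict(X) for t in TECHNIQUES]
        return np.clip(np.mean(preds, axis=0), 0.0, 1.0)


def downweight_absences(presence: np.ndarray | pd.Series) -> np.ndarray:
    """Per-record weights making total absence weight equal total presence.

    Presences get weight 1; absences n_presence / n_absence.
    """
    y = np.asarray(presence, dtype=int)
    n_pres = int((y == 1).sum())
    n_abs = int((y == 0).sum())
    if n_pres == 0 or n_abs == 0:
        raise ValueError("need at least one presence and one absence")
    w = np.where(y == 1, 1.0, n_pres / n_abs)
    return w


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, ties at half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def fit_ensemble(
    occ: pd.DataFrame,
    weights: np.ndarray | None = None,
    predictors: list[str] | None = None,
    n_rep: int = 10,
    train_frac: float = 0.8,
    seed: int | None = None,
    hyperparams: dict | None = None,
) -> SDMEnsemble:
    """Fit the four-technique ensemble with repeated 80/20 evaluation.

    Each repetition draws a seeded random calibration split, fits every
    technique on it and scores AUC on the held-out records; degenerate
    single-class held-out splits are redrawn (logged). Final members are
    refit on all records.
    """
    predictors = predictors or ["temperature"]
    hyperparams = hyperparams or {}
    y = occ["presence"].to_numpy(dtype=int)
    X = occ[predictors].to_numpy(dtype=float)
    if weights is None:
        weights = downweight_absences(y)
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("not enough records for the requested split")
    rows = []
    for rep in range(n_rep):
        for attempt in range(100):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
            logger.warning("degenerate split at repetition %d; redrawing", rep)
        else:
            raise ValueError("could not draw a split with both classes held out")
        for name in TECHNIQUES:
            member = _make_technique(name, int(rng.integers(2**31)), hyperparams)
            member.fit(X[tr], y[tr], weights[tr])
            rows.append(
                {
                    "technique": name,
                    "repetition": rep,
                    "auc": auc(member.predict(X[te]), y[te]),
                }
            )
    models = {}
    for name in TECHNIQUES:
        member = _make_technique(name, int(rng.integers(2**31)), hyperparams)
        models[name] = member.fit(X, y, weights)
    train_range = {
        p: (float(X[:, j].min()), float(X[:, j].max()))
        for j, p in enumerate(predictors)
    }
    return SDMEnsemble(
        predictors=predictors,
        models=models,
        auc_table=pd.DataFrame(rows),
        weights=weights,
        train_range=train_range,
    )


def hindcast(
    ensemble: SDMEnsemble, grids: GridSeries, technique: str | None = None
) -> GridSeries:
    """Project the ensemble onto each year's grid (mean of the four
    members, land masked, clipped to [0, 1]).

    Values outside the training range are still predicted; the number of
    extrapolated cells is logged.
    """
    if len(ensemble.predictors) != 1:
        raise ValueError("grid hindcasting supports a single gridded predictor")
    lo, hi = ensemble.train_range[ensemble.predictors[0]]
    n_extrap = 0
    layers: dict[int, np.ndarray] = {}
    for year in grids.years:
        vals = grids.sea_values(year)
        n_extrap += int(((vals < lo) | (vals > hi)).sum())
        pred = ensemble.predict(vals[:, None], technique=technique)
        layer = np.full(grids.shape, np.nan)
        layer[grids.mask] = pred
        layers[year] = layer
    if n_extrap:
        logger.warning("hindcast extrapolated beyond training range at %d cells", n_extrap)
    return GridSeries(
        years=list(grids.years),
        mask=grids.mask.copy(),
        cell_size_km=grids.cell_size_km,
        layers=layers,
    )


def occupied_temperature_summary(
    occ: pd.DataFrame, temperature_col: str = "temperature"
) -> pd.DataFrame:
    """Median, IQR and range of presence-record temperatures per population."""
    if "population" not in occ.columns:
        raise ValueError("occurrence records need a 'population' column")
    rows = []
    for pop, grp in occ[occ["presence"] == 1].groupby("population"):
        t = grp[temperature_col].to_numpy(dtype=float)
        if len(t) == 0:
            logger.warning("population %s has no presences; omitted", pop)
            continue
        q1, med, q3 = np.quantile(t, [0.25, 0.5, 0.75])
        rows.append(
            {
                "population": pop,
                "n": len(t),
                "median": med,
                "iqr": q3 - q1,
                "min": t.min(),
                "max": t.max(),
            }
        )
    return pd.DataFrame(rows)
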