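"""Synthetic data with known ground truth for every pipeline stage.

Baseline populations follow the Balding-Nichols allele-frequency model so
divergence is indexed by a single F-like parameter; mixture proportions
follow the forward simulation of the compositional state-space model;
life tables use von Bertalanffy growth and logistic maturity; temperature
grids carry a latitudinal gradient with warm/cold regime offsets; and
occurrence records are Bernoulli draws from a designed thermal response.
Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from codmix.composition import simplex_transform
from codmix.genio import GenotypeTable, GridSeries, LifeTable

logger = logging.getLogger("codmix")

PAPER_SAMPLE_YEARS = (1932, 1952, 1962, 1977, 1980, 1989, 2000, 2008, 2012)
DEFAULT_POPULATIONS = ("wg_offshore", "wg_inshore", "ice_offshore", "ice_inshore")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated scenario."""

    seed: int
    populations: list[str] = field(default_factory=list)
    baseline_freqs: np.ndarray | None = None  # (K, L) reference-allele freqs
    alpha_path: np.ndarray | None = None
    p_path: np.ndarray | None = None
    sigma: float | None = None
    sample_years: list[int] = field(default_factory=list)
    thermal_optima: dict = field(default_factory=dict)
    thermal_breadths: dict = field(default_factory=dict)
    regime_years: dict = field(default_factory=dict)
    life_table_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        Path(path).write_text(
            json.dumps({k: conv(v) for k, v in self.__dict__.items()}, indent=2)
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def gen_baselines(
    n_pops: int = 4,
    n_loci: int = 81,
    fct: float = 0.1,
    n_per_pop: int = 50,
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
) -> tuple[GenotypeTable, np.ndarray]:
    """Balding-Nichols baseline populations.

    Ancestral frequencies are Uniform(0.1, 0.9); each population draws its
    frequency from Beta with mean p and variance p(1-p)·fct. Returns the
    genotype table (with group labels) and the (K, L) true frequencies.
    """
    if not 0 < fct < 0.5:
        raise ValueError("fct must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    pops = list(populations or DEFAULT_POPULATIONS[:n_pops])
    if len(pops) != n_pops:
        raise ValueError("population name count must match n_pops")
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    theta = (1.0 - fct) / fct
    freqs = rng.beta(p_anc * theta, (1.0 - p_anc) * theta, size=(n_pops, n_loci))
    freqs = np.clip(freqs, 1e-3, 1.0 - 1e-3)
    calls = rng.binomial(2, freqs[:, None, :], size=(n_pops, n_per_pop, n_loci))
    ids, labels = [], []
    for k, pop in enumerate(pops):
        for i in range(n_per_pop):
            ids.append(f"{pop}_b{i:03d}")
            labels.append(pop)
    table = GenotypeTable(
        individual_ids=ids,
        locus_ids=[f"locus{j:03d}" for j in range(n_loci)],
        calls=calls.reshape(n_pops * n_per_pop, n_loci).astype(float),
        group_labels=labels,
    )
    return table, freqs


def gen_mixture_series(
    baseline_freqs: np.ndarray,
    sigma: float = 0.5,
    sample_years: tuple[int, ...] = PAPER_SAMPLE_YEARS,
    n_per_year: int = 100,
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
    strata: tuple[str, ...] = ("1B", "1D", "1F"),
    dt_scaling: bool = True,
) -> tuple[GenotypeTable, pd.DataFrame, SyntheticTruth]:
    """Forward-simulate the compositional state-space model.

    Draws the latent 3-D random walk (Δt-scaled innovations), maps it to
    4-simplex proportions, samples each year's individual origins from a
    multinomial and genotypes from the origin population's frequencies.
    Returns (mixed genotypes without labels, metadata, truth).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    K, L = baseline_freqs.shape
    pops = list(populations or DEFAULT_POPULATIONS[:K])
    years = np.asarray(sample_years, dtype=float)
    n = len(years)
    alpha = np.zeros((n, 3))
    for i in range(1, n):
        dt = (years[i] - years[i - 1]) if dt_scaling else 1.0
        alpha[i] = alpha[i - 1] + rng.normal(0.0, sigma * np.sqrt(dt), size=3)
    p_path = simplex_transform(alpha)
    ids, meta_rows, calls = [], [], []
    for i, year in enumerate(sample_years):
        origins = rng.choice(K, size=n_per_year, p=p_path[i])
        for j, k in enumerate(origins):
            ind = f"mix{year}_{j:03d}"
            ids.append(ind)
            meta_rows.append(
                {
                    "id": ind,
                    "year": int(year),
                    "stratum": strata[j % len(strata)],
                    "true_origin": pops[k],
                }
            )
            calls.append(rng.binomial(2, baseline_freqs[k]))
    table = GenotypeTable(
        individual_ids=ids,
        locus_ids=[f"locus{j:03d}" for j in range(L)],
        calls=np.array(calls, dtype=float),
        group_labels=None,
    )
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else -1,
        populations=pops,
        baseline_freqs=baseline_freqs,
        alpha_path=alpha,
        p_path=p_path,
        sigma=sigma,
        sample_years=[int(y) for y in sample_years],
    )
    return table, pd.DataFrame(meta_rows), truth


# ---------------------------------------------------------------------------
# life tables
# ---------------------------------------------------------------------------


def gen_life_table(
    recruit_age: int = 3,
    max_age: int = 12,
    M: float = 0.2,
    w_inf: float = 12.0,
    growth_k: float = 0.12,
    t0: float = 0.0,
    maturity_age50: float = 6.0,
    maturity_slope: float = 1.0,
    selectivity_age50: float = 4.5,
    selectivity_slope: float = 1.5,
) -> LifeTable:
    """Plausible cod-like life table: von Bertalanffy weights, logistic
    maturity and logistic selectivity."""
    ages = np.arange(recruit_age, max_age + 1)
    w = w_inf * (1.0 - np.exp(-growth_k * (ages - t0))) ** 3
    m = 1.0 / (1.0 + np.exp(-maturity_slope * (ages - maturity_age50)))
    s = 1.0 / (1.0 + np.exp(-selectivity_slope * (ages - selectivity_age50)))
    return LifeTable(ages=ages, M=np.full(len(ages), M), s=s, w=w, m=m)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def _coast_mask(nrows: int, ncols: int, rng: np.random.Generator) -> np.ndarray:
    """Sea mask with a ragged land strip along the east edge (the coast)."""
    mask = np.ones((nrows, ncols), dtype=bool)
    widths = rng.integers(1, max(2, ncols // 4), size=nrows)
    for r in range(nrows):
        mask[r, ncols - widths[r] :] = False
    return mask


def gen_environment(
    years: tuple[int, int] = (1948, 2011),
    shape: tuple[int, int] = (12, 8),
    warm_years: tuple[tuple[int, int], ...] = ((1948, 1968), (1998, 2011)),
    warm_offset: float = 2.0,
    base_south: float = 4.0,
    gradient: float = -0.4,
    noise: float = 0.3,
    cell_size_km: float = 50.0,
    seed: int = 0,
) -> tuple[GridSeries, tuple[int, int]]:
    """Yearly temperature grids with a south-north gradient and warm/cold
    regimes, plus a coastline mask and a designated southern entry cell.

    Rows run north (row 0) to south (last row); warm regimes add
    ``warm_offset`` everywhere. Returns (GridSeries, entry_cell).
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    mask = _coast_mask(nrows, ncols, rng)
    lat_field = base_south + gradient * (nrows - 1 - np.arange(nrows))[:, None]
    lat_field = np.broadcast_to(lat_field, shape).copy()
    yr_list = list(range(years[0], years[1] + 1))
    layers: dict[int, np.ndarray] = {}
    warm_flags = {}
    for y in yr_list:
        warm = any(lo <= y <= hi for lo, hi in warm_years)
        warm_flags[y] = warm
        field_y = lat_field + (warm_offset if warm else 0.0)
        field_y = field_y + rng.normal(0.0, noise, size=shape)
        field_y[~mask] = np.nan
        layers[y] = field_y
    series = GridSeries(
        years=yr_list, mask=mask, cell_size_km=cell_size_km, layers=layers
    )
    # southern entry: sea cell on the last row closest to the coast
    south_sea = np.where(mask[nrows - 1])[0]
    entry = (nrows - 1, int(south_sea[-1]))
    return series, entry


def thermal_response(
    temperature: np.ndarray, optimum: float, breadth: float
) -> np.ndarray:
    """Gaussian thermal suitability in [0, 1]."""
    t = np.asarray(temperature, dtype=float)
    return np.exp(-0.5 * ((t - optimum) / breadth) ** 2)


def gen_occurrences(
    grids: GridSeries,
    optimum: float = 4.0,
    breadth: float = 2.0,
    n_records: int = 2000,
    seed: int = 0,
    populations: dict[str, tuple[float, float]] | None = None,
    plateau: float = 1.0,
) -> pd.DataFrame:
    """Presence/absence records sampled uniformly over sea cells and years.

    Presence is Bernoulli with probability ``plateau`` times the Gaussian
    thermal response; when ``populations`` maps labels to (optimum, breadth),
    each presence is additionally labelled by the population whose
    response most likely produced it.
    """
    if n_records <= 0:
        raise ValueError("n_records must be > 0")
    rng = np.random.default_rng(seed)
    sea = np.argwhere(grids.mask)
    rows = []
    for _ in range(n_records):
        year = int(rng.choice(grids.years))
        r, c = sea[rng.integers(len(sea))]
        temp = grids.layers[year][r, c]
        prob = plateau * float(thermal_response(temp, optimum, breadth))
        pres = int(rng.random() < prob)
        row = {
            "year": year,
            "row": int(r),
            "col": int(c),
            "temperature": float(temp),
            "presence": pres,
        }
        if populations and pres:
            labels = list(populations)
            probs = np.array(
                [thermal_response(temp, *populations[lab]) for lab in labels]
            )
            probs = probs / probs.sum()
            row["population"] = labels[rng.choice(len(labels), p=probs)]
        rows.append(row)
    return pd.DataFrame(rows)


def gen_stratum_counts(
    distances: np.ndarray,
    n_per_stratum: int = 200,
    intercept: float = 2.0,
    slope: float = -0.04,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial stratum counts with logit(π) = intercept + slope·distance.

    Returns (successes, totals) per stratum — the forward model behind the
    proportion-vs-distance GLM.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(distances, dtype=float)
    pi = 1.0 / (1.0 + np.exp(-(intercept + slope * d)))
    totals = np.full(len(d), n_per_stratum)
    successes = rng.binomial(totals, pi)
    return successes, totals


def gen_biomass_series(
    years: tuple[int, int] = (1950, 2012),
    peak: float = 450_000.0,
    collapse_year: int = 1972,
    seed: int = 0,
) -> pd.Series:
    """Total 3+ biomass series (tonnes): boom, collapse, weak rebound."""
    rng = np.random.default_rng(seed)
    yr = np.arange(years[0], years[1] + 1)
    level = np.where(
        yr < collapse_year,
        peak * np.exp(-0.5 * ((yr - 1960) / 10.0) ** 2),
        peak * 0.05 * (1 + 0.5 * np.tanh((yr - 2000) / 10.0)),
    )
    level = level * np.exp(rng.normal(0, 0.05, size=len(yr)))
    return pd.Series(level, index=pd.Index(yr.astype(float), name="year"), name="biomass")
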