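"""Spawning-stock-biomass-per-recruit and equilibrium fishing mortality.

Survivorship per recruit follows N_{a+1} = N_a exp(-(F·s_a + M_a)) with one
fish at the recruit age; SSB/R multiplies survivors by weight- and
maturity-at-age. The equilibrium F is the root of ssbr(F) = target on a
fishing pattern normalized so mean selectivity over the reporting ages is
one, making the multiplier directly the reported mean F.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from codmix.genio import LifeTable

logger = logging.getLogger("codmix")

F_MAX = 10.0  # equilibrium F above this treated as unattainable


@dataclass
class PerRecruitResult:
    F_mult: float
    F_bar: float  # mean F over the reporting ages
    N_a: np.ndarray  # survivors-at-age per recruit
    ssbr: float  # kg of spawning biomass per recruit


def normalize_pattern(lt: LifeTable, report_ages: tuple[int, int] = (5, 12)) -> LifeTable:
    """Rescale s_a so its mean over the reporting ages equals 1."""
    lo, hi = report_ages
    sel = (lt.ages >= lo) & (lt.ages <= hi)
    if not sel.any():
        raise ValueError("reporting ages outside the life table")
    mean_s = lt.s[sel].mean()
    if mean_s <= 0:
        raise ValueError("fishing pattern has zero mean over the reporting ages")
    return LifeTable(ages=lt.ages, M=lt.M, s=lt.s / mean_s, w=lt.w, m=lt.m)


def survivorship(F_mult: float, lt: LifeTable) -> np.ndarray:
    """Numbers alive at each age per one recruit at the first age."""
    if F_mult < 0:
        raise ValueError("fishing mortality multiplier must be >= 0")
    Z = F_mult * lt.s + lt.M
    N = np.empty(lt.n_ages)
    N[0] = 1.0
    N[1:] = np.exp(-np.cumsum(Z[:-1]))
    return N


def ssb_per_recruit(F_mult: float, lt: LifeTable, spawn_fraction: float = 0.0) -> float:
    """Spawning biomass (kg) produced per recruit at fishing multiplier F.

    ``spawn_fraction`` applies a within-year mortality fraction before
    spawning (0 = beginning-of-year abundance, the default).
    """
    N = survivorship(F_mult, lt)
    if spawn_fraction > 0:
        Z = F_mult * lt.s + lt.M
        N = N * np.exp(-spawn_fraction * Z)
    return float(np.sum(N * lt.w * lt.m))


def per_recruit_curve(
    lt: LifeTable,
    F_grid: np.ndarray,
    report_ages: tuple[int, int] = (5, 12),
) -> list[PerRecruitResult]:
    lt = normalize_pattern(lt, report_ages)
    lo, hi = report_ages
    sel = (lt.ages >= lo) & (lt.ages <= hi)
    out = []
    for F in F_grid:
        N = survivorship(F, lt)
        out.append(
            PerRecruitResult(
                F_mult=float(F),
                F_bar=float(F * lt.s[sel].mean()),
                N_a=N,
                ssbr=float(np.sum(N * lt.w * lt.m)),
            )
        )
    return out


def solve_feq(
    target_ssbr: float,
    lt: LifeTable,
    report_ages: tuple[int, int] = (5, 12),
    spawn_fraction: float = 0.0,
) -> float:
    """Equilibrium mean F over the reporting ages for a replacement SSB/R.

    Solves ssbr(F) = target by bracketed root finding on [0, 10]; with the
    normalized pattern the multiplier equals the reported mean F.
    """
    if target_ssbr <= 0:
        raise ValueError("target SSB/R must be > 0")
    lt = normalize_pattern(lt, report_ages)
    virgin = ssb_per_recruit(0.0, lt, spawn_fraction)
    if target_ssbr >= virgin:
        raise ValueError(
            f"stock cannot replace itself at F=0: target {target_ssbr} >= "
            f"unfished SSB/R {virgin:.6g}"
        )
    f = lambda F: ssb_per_recruit(F, lt, spawn_fraction) - target_ssbr
    if f(F_MAX) > 0:
        raise ValueError(f"equilibrium F above {F_MAX} treated as unattainable")
    root = brentq(f, 0.0, F_MAX, xtol=1e-12, rtol=1e-14)
    # polish until |Δssbr| < 1e-9 * target
    assert abs(f(root)) < 1e-9 * target_ssbr + 1e-12
    return float(root)


def replacement_ssbr(
    ssb_series: dict | "np.ndarray",
    recruit_series: dict,
    recruit_age: int = 3,
) -> float:
    """Mean SSB needed per recruit: average of SSB_t / R_{t+recruit_age}.

    Years with zero recruitment are skipped with a warning.
    """
    ratios = []
    for year, ssb in dict(ssb_series).items():
        r_year = year + recruit_age
        if r_year not in recruit_series:
            continue
        r = recruit_series[r_year]
        if r == 0:
            warnings.warn(f"zero recruitment in {r_year}; year {year} skipped")
            continue
        ratios.append(ssb / r)
    if not ratios:
        raise ValueError("no overlapping SSB/recruitment years after lagging")
    return float(np.mean(ratios))


def sensitivity_scan(
    lt: LifeTable,
    target_ssbr: float,
    reference_feq: float,
    mode: str = "ssb_scale",
    report_ages: tuple[int, int] = (5, 12),
    k_grid: np.ndarray | None = None,
):
    """Sensitivity of the equilibrium F to input errors.

    ``ssb_scale`` solves for the factor k by which SSB (hence the SSB/R
    target) must have been overestimated for the true equilibrium F to
    equal ``reference_feq``; the other modes multiply the weight or
    maturity schedule by each k in ``k_grid`` and report the F_eq
    response curve.
    """
    if mode == "ssb_scale":
        if reference_feq > F_MAX:
            raise ValueError(f"reference F_eq above the attainable cap {F_MAX}")

        def gap(k: float) -> float:
            # F_eq beyond the cap means the scaled target is exceedingly
            # easy to reach: the gap is effectively +infinity
            try:
                return solve_feq(target_ssbr / k, lt, report_ages) - reference_feq
            except ValueError:
                return F_MAX - reference_feq + 1.0

        lo, hi = 1.0, 100.0
        g_lo = gap(lo)
        if g_lo > 1e-12:
            raise ValueError("reference F_eq below the unscaled equilibrium F")
        if gap(hi) < 0:
            raise ValueError(
                f"reference F_eq {reference_feq} unattainable for k in [1, 100]"
            )
        if g_lo >= -1e-12:
            return 1.0
        k = brentq(gap, lo, hi, xtol=1e-10)
        return float(k)
    if mode in ("growth_shift", "maturity_shift", "recruitment_scale"):
        if k_grid is None:
            k_grid = np.linspace(0.5, 2.0, 16)
        curve = []
        for k in k_grid:
            if mode == "growth_shift":
                lt_k = LifeTable(lt.ages, lt.M, lt.s, lt.w * k, lt.m)
                tgt = target_ssbr
            elif mode == "maturity_shift":
                lt_k = LifeTable(lt.ages, lt.M, lt.s, lt.w, np.clip(lt.m * k, 0, 1))
                tgt = target_ssbr
            else:  # recruitment_scale: R overestimated by k -> target scaled by k
                lt_k = lt
                tgt = target_ssbr * k
            try:
                feq = solve_feq(tgt, lt_k, report_ages)
            except ValueError:
                feq = np.nan
            curve.append((float(k), feq))
        return curve
    raise ValueError(f"unknown sensitivity mode '{mode}'")
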