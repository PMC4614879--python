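"""Genetic stock identification against baseline spawning populations.

Two independent assignment routes — a compound-Dirichlet genotype
likelihood with Monte-Carlo exclusion testing, and discriminant analysis
of principal components — combined by a strict dual high-probability
consensus rule, plus among-group F_CT locus ranking for panel reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from codmix.genio import CatchCountTable, GenotypeTable

logger = logging.getLogger("codmix")

DISCARDED = "DISCARDED"


@dataclass
class BaselineFrequencies:
    """Per-locus reference-allele counts for K baseline populations.

    ``x[k, j]`` is the reference-allele count and ``n[k, j]`` the number of
    typed gene copies (2 x typed individuals) for population k at locus j.
    """

    populations: list[str]
    locus_ids: list[str]
    x: np.ndarray  # (K, L) reference allele counts
    n: np.ndarray  # (K, L) typed gene copies

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.x.shape != (len(self.populations), len(self.locus_ids)):
            raise ValueError("x shape mismatch")
        if self.n.shape != self.x.shape:
            raise ValueError("n shape mismatch")
        if ((self.x < 0) | (self.x > self.n)).any():
            raise ValueError("allele counts must satisfy 0 <= x <= n")

    @property
    def K(self) -> int:
        return len(self.populations)

    def posterior_mean_freq(self) -> np.ndarray:
        """Posterior-mean reference-allele frequency under the Dirichlet(1/2, 1/2) prior."""
        return (self.x + 0.5) / (self.n + 1.0)


@dataclass
class AssignmentResult:
    """Membership calls for one mixed-stock individual."""

    individual_id: str
    bayes_posteriors: np.ndarray
    exclusion_pvalues: np.ndarray
    dapc_posteriors: np.ndarray
    consensus: str

    def __post_init__(self) -> None:
        for v in (self.bayes_posteriors, self.dapc_posteriors):
            if abs(float(np.sum(v)) - 1.0) > 1e-9:
                raise ValueError("posterior vector must sum to 1")


def allele_frequencies(baseline: GenotypeTable) -> BaselineFrequencies:
    """Tally reference-allele counts per locus per labelled population."""
    if baseline.group_labels is None:
        raise ValueError("baseline table must carry group labels")
    pops = sorted(set(baseline.group_labels))
    labels = np.array(baseline.group_labels)
    K, L = len(pops), baseline.n_loci
    x = np.zeros((K, L))
    n = np.zeros((K, L))
    for k, pop in enumerate(pops):
        calls = baseline.calls[labels == pop]
        typed = ~np.isnan(calls)
        x[k] = np.nansum(calls, axis=0)
        n[k] = 2.0 * typed.sum(axis=0)
        if n[k].sum() == 0:
            raise ValueError(f"population {pop} has no typed individuals at any locus")
    return BaselineFrequencies(populations=pops, locus_ids=list(baseline.locus_ids), x=x, n=n)


def fct_rank_loci(
    baseline: BaselineFrequencies, groups: list[list[str]]
) -> pd.DataFrame:
    """Rank loci by among-group fixation index F_CT, descending.

    Group allele frequencies are weighted by typed gene copies; F_CT at a
    locus is the weighted variance of group frequencies over p̄(1 − p̄).
    Monomorphic loci get F_CT = 0.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 population each")
    pop_index = {p: i for i, p in enumerate(baseline.populations)}
    L = len(baseline.locus_ids)
    fct = np.zeros(L)
    g_x = np.array(
        [baseline.x[[pop_index[p] for p in g]].sum(axis=0) for g in groups]
    )
    g_n = np.array(
        [baseline.n[[pop_index[p] for p in g]].sum(axis=0) for g in groups]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        g_p = np.where(g_n > 0, g_x / np.maximum(g_n, 1e-300), np.nan)
    for j in range(L):
        w = g_n[:, j]
        p = g_p[:, j]
        ok = w > 0
        if ok.sum() < 2:
            continue
        w, p = w[ok], p[ok]
        pbar = np.average(p, weights=w)
        denom = pbar * (1.0 - pbar)
        if denom <= 0:
            continue  # monomorphic -> 0
        var = np.average((p - pbar) ** 2, weights=w)
        fct[j] = var / denom
    df = pd.DataFrame({"locus": baseline.locus_ids, "fct": fct})
    return df.sort_values("fct", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def select_top_loci(ranked: pd.DataFrame, k: int) -> list[str]:
    """Top-k loci from an :func:`fct_rank_loci` ranking."""
    return list(ranked["locus"].head(k))


# ---------------------------------------------------------------------------
# compound-Dirichlet genotype likelihood
# ---------------------------------------------------------------------------


def _locus_genotype_logprobs(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Log probability of dosage {0,1,2} per locus under the posterior-
    predictive genotype distribution with a symmetric Dirichlet(1/2, 1/2)
    prior on the two allele frequencies.

    Returns array of shape x.shape + (3,), ordered by reference dosage.
    """
    c_ref = x + 0.5
    c_alt = (n - x) + 0.5
    C = n + 1.0
    norm = C * (C + 1.0)
    p_hom_alt = c_alt * (c_alt + 1.0) / norm
    p_het = 2.0 * c_ref * c_alt / norm
    p_hom_ref = c_ref * (c_ref + 1.0) / norm
    return np.log(np.stack([p_hom_alt, p_het, p_hom_ref], axis=-1))


def rm_genotype_loglik(genotype: np.ndarray, baseline: BaselineFrequencies) -> np.ndarray:
    """Multilocus genotype log-likelihood under each baseline population.

    ``genotype`` is a length-L dosage vector (NaN = missing, skipped).
    Returns a length-K vector of log-likelihoods.
    """
    genotype = np.asarray(genotype, dtype=float)
    typed = ~np.isnan(genotype)
    if not typed.any():
        raise ValueError("individual typed at zero loci")
    dose = genotype[typed].astype(int)
    logp = _locus_genotype_logprobs(baseline.x[:, typed], baseline.n[:, typed])
    return logp[:, np.arange(dose.size), dose].sum(axis=1)


def bayes_assign(genotype: np.ndarray, baseline: BaselineFrequencies) -> np.ndarray:
    """Posterior membership over populations with equal priors."""
    ll = rm_genotype_loglik(genotype, baseline)
    ll = ll - ll.max()
    w = np.exp(ll)
    return w / w.sum()


def mc_exclusion_test(
    genotype: np.ndarray,
    baseline: BaselineFrequencies,
    n_sim: int = 10000,
    alpha: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo exclusion p-values for each candidate population.

    For each population, ``n_sim`` individuals are simulated from the
    posterior-mean allele frequencies at the loci typed in the observed
    genotype; the p-value is the +1-corrected fraction of simulated
    log-likelihoods at or below the observed one. Returns (p_values,
    excluded) with excluded = p < alpha.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genotype = np.asarray(genotype, dtype=float)
    typed = ~np.isnan(genotype)
    if not typed.any():
        raise ValueError("individual typed at zero loci")
    obs_ll = rm_genotype_loglik(genotype, baseline)
    freqs = baseline.posterior_mean_freq()[:, typed]  # (K, Lt)
    logp = _locus_genotype_logprobs(baseline.x[:, typed], baseline.n[:, typed])
    pvals = np.empty(baseline.K)
    for k in range(baseline.K):
        doses = rng.binomial(2, freqs[k], size=(n_sim, typed.sum()))
        sim_ll = logp[k, np.arange(typed.sum()), doses].sum(axis=1)
        pvals[k] = (1.0 + np.sum(sim_ll <= obs_ll[k])) / (n_sim + 1.0)
    return pvals, pvals < alpha


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


@dataclass
class DAPCModel:
    """Discriminant analysis of principal components, fitted on dosages."""

    locus_ids: list[str]
    populations: list[str]
    col_means: np.ndarray  # imputation + centering vector, frequency scale
    col_scales: np.ndarray
    pc_axes: np.ndarray  # (L, n_pcs)
    lda: LinearDiscriminantAnalysis
    n_da: int
    centroids: np.ndarray  # (K, n_da) in discriminant space

    def _embed(self, table: GenotypeTable) -> np.ndarray:
        overlap = [l for l in self.locus_ids if l in table.locus_ids]
        if not overlap:
            raise ValueError("no overlapping loci between model and genotypes")
        col = {l: j for j, l in enumerate(table.locus_ids)}
        X = np.full((table.n_individuals, len(self.locus_ids)), np.nan)
        for j, l in enumerate(self.locus_ids):
            if l in col:
                X[:, j] = table.calls[:, col[l]]
        X = X / 2.0  # frequency scale
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(self.col_means, X.shape)[miss]
        Xc = (X - self.col_means) / self.col_scales
        pcs = Xc @ self.pc_axes
        return self.lda.transform(pcs)[:, : self.n_da]


def dapc_fit(
    baseline: GenotypeTable, n_pcs: int | None = None, n_da: int | None = None
) -> DAPCModel:
    """Fit PCA + linear discriminant axes on baseline dosage frequencies.

    Missing calls are imputed to the locus mean. Defaults: ``n_pcs`` =
    number of PCs explaining 90% of variance capped at n/3; ``n_da`` =
    K − 1.
    """
    if baseline.group_labels is None:
        raise ValueError("baseline table must carry group labels")
    labels = np.array(baseline.group_labels)
    pops = sorted(set(labels))
    if len(pops) < 2:
        raise ValueError("need at least two groups to fit a discriminant model")
    for pop in pops:
        if (labels == pop).sum() < 2:
            raise ValueError(f"group {pop} has <2 individuals")
    X = baseline.calls / 2.0
    col_means = np.nanmean(X, axis=0)
    miss = np.isnan(X)
    X = np.where(miss, np.broadcast_to(col_means, X.shape), X)
    col_scales = np.ones(X.shape[1])
    Xc = X - col_means
    # PCA via SVD
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    explained = np.cumsum(var) / var.sum()
    if n_pcs is None:
        n_pcs = int(np.searchsorted(explained, 0.90) + 1)
        n_pcs = min(n_pcs, max(1, baseline.n_individuals // 3))
    if n_pcs >= baseline.n_individuals:
        raise ValueError("n_pcs must be < number of baseline individuals")
    n_pcs = min(n_pcs, Vt.shape[0])
    pc_axes = Vt[:n_pcs].T
    pcs = Xc @ pc_axes
    if n_da is None:
        n_da = len(pops) - 1
    if n_da > len(pops) - 1:
        raise ValueError("n_da must be <= K - 1")
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    lda.fit(pcs, labels)
    da = lda.transform(pcs)[:, :n_da]
    centroids = np.vstack([da[labels == pop].mean(axis=0) for pop in pops])
    return DAPCModel(
        locus_ids=list(baseline.locus_ids),
        populations=pops,
        col_means=col_means,
        col_scales=col_scales,
        pc_axes=pc_axes,
        lda=lda,
        n_da=n_da,
        centroids=centroids,
    )


def dapc_predict(model: DAPCModel, genotypes: GenotypeTable) -> np.ndarray:
    """Membership probabilities from discriminant-space distances.

    membership_k ∝ exp(−0.5 d_k²) with d_k the Euclidean distance to
    centroid k, equal priors and identity covariance.
    """
    da = model._embed(genotypes)
    d2 = ((da[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    logw = -0.5 * d2
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# consensus and tabulation
# ---------------------------------------------------------------------------


def consensus_assign(
    bayes: np.ndarray,
    dapc: np.ndarray,
    populations: list[str],
    threshold: float = 0.90,
) -> str:
    """Strict dual-threshold consensus: a label is returned only when both
    methods put strictly more than ``threshold`` probability on the same
    population; otherwise DISCARDED."""
    bayes = np.asarray(bayes)
    dapc = np.asarray(dapc)
    if bayes.shape != dapc.shape or len(bayes) != len(populations):
        raise ValueError("posterior vectors must both have length K")
    k = int(np.argmax(bayes))
    if bayes[k] > threshold and dapc[k] > threshold:
        return populations[k]
    return DISCARDED


def assign_all(
    baseline: GenotypeTable,
    mixed: GenotypeTable,
    threshold: float = 0.90,
    n_sim: int = 10000,
    alpha: float = 0.01,
    seed: int | None = None,
    run_exclusion: bool = True,
) -> list[AssignmentResult]:
    """Full two-method assignment of every mixed-stock individual."""
    freqs = allele_frequencies(baseline)
    model = dapc_fit(baseline)
    if model.populations != freqs.populations:
        raise RuntimeError("population ordering mismatch between methods")
    dapc_post = dapc_predict(model, mixed)
    rng = np.random.default_rng(seed)
    results = []
    for i, ind in enumerate(mixed.individual_ids):
        bayes = bayes_assign(mixed.calls[i], freqs)
        if run_exclusion:
            pvals, _ = mc_exclusion_test(
                mixed.calls[i], freqs, n_sim=n_sim, alpha=alpha, seed=rng
            )
        else:
            pvals = np.ones(freqs.K)
        label = consensus_assign(bayes, dapc_post[i], freqs.populations, threshold)
        results.append(
            AssignmentResult(
                individual_id=ind,
                bayes_posteriors=bayes,
                exclusion_pvalues=pvals,
                dapc_posteriors=dapc_post[i],
                consensus=label,
            )
        )
    return results


def tabulate_composition(
    assignments: list[AssignmentResult], metadata: pd.DataFrame
) -> tuple[CatchCountTable, dict]:
    """Count consensus labels per (year, stratum) and report retention.

    ``metadata`` must have columns id, year, stratum covering every
    assigned individual. Discarded individuals are excluded from counts;
    empty strata do not appear.
    """
    meta = metadata.set_index("id")
    for r in assignments:
        if r.individual_id not in meta.index:
            raise ValueError(f"metadata missing for individual {r.individual_id}")
    pops = sorted(
        {r.consensus for r in assignments if r.consensus != DISCARDED}
    )
    cells: dict[tuple[float, str], np.ndarray] = {}
    n_disc = 0
    for r in assignments:
        if r.consensus == DISCARDED:
            n_disc += 1
            continue
        row = meta.loc[r.individual_id]
        key = (float(row["year"]), str(row["stratum"]))
        cells.setdefault(key, np.zeros(len(pops), dtype=int))
        cells[key][pops.index(r.consensus)] += 1
    keys = sorted(cells)
    table = CatchCountTable(
        times=np.array([k[0] for k in keys]),
        strata=[k[1] for k in keys],
        populations=pops,
        counts=np.vstack([cells[k] for k in keys]) if keys else np.zeros((0, len(pops)), dtype=int),
    )
    total = len(assignments)
    report = {
        "total": total,
        "discarded": n_disc,
        "retained_fraction": 1.0 - n_disc / total if total else float("nan"),
    }
    return table, report


def results_to_frame(results: list[AssignmentResult], populations: list[str]) -> pd.DataFrame:
    """Tidy per-individual CSV layout: id, per-method posteriors, consensus."""
    rows = []
    for r in results:
        row: dict = {"id": r.individual_id}
        for j, p in enumerate(populations, start=1):
            row[f"bayes_p{j}"] = r.bayes_posteriors[j - 1]
        for j in range(1, len(populations) + 1):
            row[f"dapc_p{j}"] = r.dapc_posteriors[j - 1]
        for j in range(1, len(populations) + 1):
            row[f"excl_p{j}"] = r.exclusion_pvalues[j - 1]
        row["consensus"] = r.consensus
        rows.append(row)
    return pd.DataFrame(rows)
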