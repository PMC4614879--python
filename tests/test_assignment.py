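import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from codmix import synthdata
from codmix.assignment import (
    DISCARDED,
    BaselineFrequencies,
    _locus_genotype_logprobs,
    allele_frequencies,
    assign_all,
    bayes_assign,
    consensus_assign,
    dapc_fit,
    dapc_predict,
    fct_rank_loci,
    mc_exclusion_test,
    rm_genotype_loglik,
    select_top_loci,
    tabulate_composition,
)
from codmix.genio import GenotypeTable


def _bf(x, n, populations=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    pops = populations or [f"P{i}" for i in range(x.shape[0])]
    loci = [f"L{j}" for j in range(x.shape[1])]
    return BaselineFrequencies(populations=pops, locus_ids=loci, x=x, n=n)


class TestAlleleFrequencies:
    def test_homozygote_tally(self):
        t = GenotypeTable(
            ["a", "b"], ["L1"], np.array([[2.0], [2.0]]), group_labels=["P", "P"]
        )
        bf = allele_frequencies(t)
        assert bf.x[0, 0] == 4 and bf.n[0, 0] == 4

    def test_missing_reduces_n(self):
        t = GenotypeTable(
            ["a", "b"], ["L1"], np.array([[1.0], [np.nan]]), group_labels=["P", "P"]
        )
        bf = allele_frequencies(t)
        assert bf.n[0, 0] == 2 and bf.x[0, 0] == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(5, 3)).astype(float)
        calls[rng.random((5, 3)) < 0.2] = np.nan
        labels = ["P1", "P1", "P2", "P2", "P2"]
        t = GenotypeTable(
            [f"i{k}" for k in range(5)], ["L1", "L2", "L3"], calls, group_labels=labels
        )
        bf = allele_frequencies(t)
        # independent per-genotype tally
        for k, pop in enumerate(bf.populations):
            for j in range(3):
                x = n = 0
                for i in range(5):
                    if labels[i] == pop and not np.isnan(calls[i, j]):
                        x += int(calls[i, j])
                        n += 2
                assert bf.x[k, j] == x and bf.n[k, j] == n

    def test_requires_labels(self, tiny_table):
        tiny_table.group_labels = None
        with pytest.raises(ValueError):
            allele_frequencies(tiny_table)


class TestFctRank:
    def test_fixed_difference_is_one(self):
        bf = _bf([[100], [0]], [[100], [100]])
        ranked = fct_rank_loci(bf, [["P0"], ["P1"]])
        assert ranked["fct"].iloc[0] == pytest.approx(1.0)

    def test_identical_frequencies_zero(self):
        bf = _bf([[50], [50]], [[100], [100]])
        ranked = fct_rank_loci(bf, [["P0"], ["P1"]])
        assert ranked["fct"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_ranking_order(self):
        # group freqs per locus: (0.9,0.1), (0.6,0.4), (0.5,0.5) on n=100
        bf = _bf(
            [[90, 60, 50], [10, 40, 50]],
            [[100, 100, 100], [100, 100, 100]],
        )
        ranked = fct_rank_loci(bf, [["P0"], ["P1"]])
        assert list(ranked["locus"]) == ["L0", "L1", "L2"]
        # direct formula evaluation oracle
        expect = []
        for pa, pb in [(0.9, 0.1), (0.6, 0.4), (0.5, 0.5)]:
            pbar = (pa + pb) / 2
            var = ((pa - pbar) ** 2 + (pb - pbar) ** 2) / 2
            expect.append(var / (pbar * (1 - pbar)) if pbar * (1 - pbar) else 0.0)
        np.testing.assert_allclose(
            ranked.set_index("locus").loc[["L0", "L1", "L2"], "fct"], expect
        )

    def test_top_k(self):
        bf = _bf([[90, 60], [10, 40]], [[100, 100], [100, 100]])
        ranked = fct_rank_loci(bf, [["P0"], ["P1"]])
        assert select_top_loci(ranked, 1) == ["L0"]

    def test_needs_two_groups(self):
        bf = _bf([[1]], [[2]])
        with pytest.raises(ValueError):
            fct_rank_loci(bf, [["P0"]])


class TestGenotypeLikelihood:
    def test_prior_only_probabilities(self):
        logp = _locus_genotype_logprobs(np.array([0.0]), np.array([0.0]))
        probs = np.exp(logp[0])
        np.testing.assert_allclose(probs, [0.375, 0.25, 0.375])
        assert probs.sum() == pytest.approx(1.0)

    def test_fixed_reference_limit(self):
        for n in (10, 100, 10000):
            logp = _locus_genotype_logprobs(np.array([float(n)]), np.array([float(n)]))
            expect = (n + 0.5) * (n + 1.5) / ((n + 1) * (n + 2))
            assert np.exp(logp[0, 2]) == pytest.approx(expect)
        assert expect > 0.999

    def test_matches_quadrature(self):
        # P(hom ref) = E[theta^2] under the Beta(x+1/2, n-x+1/2) posterior
        x, n = 3, 8
        a, b = x + 0.5, n - x + 0.5
        hom_ref, _ = quad(lambda th: th**2 * beta_dist.pdf(th, a, b), 0, 1)
        het, _ = quad(lambda th: 2 * th * (1 - th) * beta_dist.pdf(th, a, b), 0, 1)
        logp = _locus_genotype_logprobs(np.array([float(x)]), np.array([float(n)]))
        assert np.exp(logp[0, 2]) == pytest.approx(hom_ref, rel=1e-8)
        assert np.exp(logp[0, 1]) == pytest.approx(het, rel=1e-8)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_single_locus_probs_sum_to_one(self, x, n):
        x = min(x, n)
        logp = _locus_genotype_logprobs(np.array([float(x)]), np.array([float(n)]))
        assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_missing_errors(self):
        bf = _bf([[1]], [[2]])
        with pytest.raises(ValueError, match="zero loci"):
            rm_genotype_loglik(np.array([np.nan]), bf)

    def test_missing_loci_skipped(self):
        bf = _bf([[5, 5]], [[10, 10]])
        full = rm_genotype_loglik(np.array([1.0, np.nan]), bf)
        partial = rm_genotype_loglik(np.array([1.0]), _bf([[5]], [[10]]))
        assert full[0] == pytest.approx(partial[0])


class TestBayesAssign:
    def test_identical_baselines_symmetric(self):
        bf = _bf([[5, 3], [5, 3]], [[10, 10], [10, 10]])
        post = bayes_assign(np.array([2.0, 1.0]), bf)
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_fixed_difference_confident(self):
        L = 10
        bf = _bf(
            [np.full(L, 100.0), np.zeros(L)],
            [np.full(L, 100.0), np.full(L, 100.0)],
        )
        post = bayes_assign(np.full(L, 2.0), bf)
        assert post[0] > 0.999

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        n = np.full((3, 6), 40.0)
        x = rng.integers(0, 41, size=(3, 6)).astype(float)
        bf = _bf(x, n)
        geno = rng.integers(0, 3, size=6).astype(float)
        assert bayes_assign(geno, bf).sum() == pytest.approx(1.0, abs=1e-12)

    def test_locus_order_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 21, size=(2, 5)).astype(float)
        bf = _bf(x, np.full((2, 5), 20.0))
        geno = rng.integers(0, 3, size=5).astype(float)
        perm = rng.permutation(5)
        bf_p = _bf(x[:, perm], np.full((2, 5), 20.0))
        np.testing.assert_allclose(
            bayes_assign(geno, bf), bayes_assign(geno[perm], bf_p), atol=1e-12
        )

    def test_uninformative_locus_invariance(self):
        bf = _bf([[8, 2], [2, 2]], [[10, 10], [10, 10]])
        bf_small = _bf([[8], [2]], [[10], [10]])
        post_full = bayes_assign(np.array([2.0, 1.0]), bf)
        post_small = bayes_assign(np.array([2.0]), bf_small)
        np.testing.assert_allclose(post_full, post_small, atol=1e-12)


class TestExclusionTest:
    def test_p_value_bounds(self):
        bf = _bf([[5, 2]], [[10, 10]])
        p, _ = mc_exclusion_test(np.array([1.0, 0.0]), bf, n_sim=200, seed=0)
        assert (p >= 1 / 201).all() and (p <= 1.0).all()

    def test_extreme_tail_excluded(self):
        L = 20
        bf = _bf([np.full(L, 199.0)], [np.full(L, 200.0)])
        p, excl = mc_exclusion_test(np.zeros(L), bf, n_sim=1000, seed=1)
        assert p[0] < 0.01 and excl[0]

    def test_min_nsim(self):
        bf = _bf([[5]], [[10]])
        with pytest.raises(ValueError):
            mc_exclusion_test(np.array([1.0]), bf, n_sim=50)

    def test_determinism(self):
        bf = _bf([[5, 2]], [[10, 10]])
        p1, _ = mc_exclusion_test(np.array([1.0, 0.0]), bf, n_sim=500, seed=7)
        p2, _ = mc_exclusion_test(np.array([1.0, 0.0]), bf, n_sim=500, seed=7)
        np.testing.assert_array_equal(p1, p2)


class TestDAPC:
    def test_separated_groups(self):
        rng = np.random.default_rng(3)
        table, _ = synthdata.gen_baselines(
            n_pops=2, n_loci=60, fct=0.2, n_per_pop=25, seed=3
        )
        model = dapc_fit(table)
        da = model._embed(table)
        labels = np.array(table.group_labels)
        g0, g1 = da[labels == model.populations[0], 0], da[labels == model.populations[1], 0]
        sep = abs(g0.mean() - g1.mean())
        within = np.sqrt((g0.var() + g1.var()) / 2)
        assert sep > 5 * within

    def test_single_group_errors(self):
        t = GenotypeTable(
            ["a", "b"], ["L1"], np.array([[0.0], [1.0]]), group_labels=["P", "P"]
        )
        with pytest.raises(ValueError):
            dapc_fit(t)

    def test_small_group_errors(self):
        t = GenotypeTable(
            ["a", "b", "c"],
            ["L1"],
            np.array([[0.0], [1.0], [2.0]]),
            group_labels=["P1", "P1", "P2"],
        )
        with pytest.raises(ValueError, match="<2"):
            dapc_fit(t)

    def test_predict_sums_to_one_and_confident_at_centroid(self, baseline_pair):
        table, _ = baseline_pair
        model = dapc_fit(table)
        memb = dapc_predict(model, table)
        np.testing.assert_allclose(memb.sum(axis=1), 1.0, atol=1e-9)
        labels = np.array(table.group_labels)
        acc = np.mean(
            [model.populations[np.argmax(memb[i])] == labels[i] for i in range(len(labels))]
        )
        assert acc > 0.95

    def test_equidistant_point_is_symmetric(self):
        table, _ = synthdata.gen_baselines(
            n_pops=2, n_loci=30, fct=0.2, n_per_pop=20, seed=9
        )
        model = dapc_fit(table)
        # synthesize an embedding exactly between centroids
        mid = model.centroids.mean(axis=0)
        d2 = ((mid - model.centroids) ** 2).sum(axis=1)
        w = np.exp(-0.5 * d2)
        w = w / w.sum()
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_no_overlapping_loci(self, baseline_pair):
        table, _ = baseline_pair
        model = dapc_fit(table)
        other = GenotypeTable(["z"], ["unknown"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="overlap"):
            dapc_predict(model, other)


class TestConsensus:
    def test_agreeing_confident(self):
        lab = consensus_assign(
            np.array([0.95, 0.05]), np.array([0.92, 0.08]), ["A", "B"]
        )
        assert lab == "A"

    def test_disagreeing_discarded(self):
        lab = consensus_assign(
            np.array([0.95, 0.05]), np.array([0.05, 0.95]), ["A", "B"]
        )
        assert lab == DISCARDED

    def test_below_threshold_discarded(self):
        lab = consensus_assign(
            np.array([0.89, 0.11]), np.array([0.99, 0.01]), ["A", "B"]
        )
        assert lab == DISCARDED

    def test_strictly_greater(self):
        lab = consensus_assign(
            np.array([0.90, 0.10]), np.array([0.95, 0.05]), ["A", "B"]
        )
        assert lab == DISCARDED

    def test_never_labels_below_threshold(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            b = rng.dirichlet(np.ones(4))
            d = rng.dirichlet(np.ones(4))
            lab = consensus_assign(b, d, ["A", "B", "C", "D"])
            if lab != DISCARDED:
                k = ["A", "B", "C", "D"].index(lab)
                assert b[k] > 0.90 and d[k] > 0.90


class TestTabulate:
    def _results(self):
        from codmix.assignment import AssignmentResult

        res = []
        labels = ["A", "A", "B", DISCARDED, "B", "A", DISCARDED, "B", "A", "B"]
        for i, lab in enumerate(labels):
            res.append(
                AssignmentResult(
                    individual_id=f"i{i}",
                    bayes_posteriors=np.array([0.95, 0.05]),
                    exclusion_pvalues=np.array([0.5, 0.5]),
                    dapc_posteriors=np.array([0.95, 0.05]),
                    consensus=lab,
                )
            )
        return res

    def _meta(self):
        return pd.DataFrame(
            {
                "id": [f"i{i}" for i in range(10)],
                "year": [1950] * 5 + [1960] * 5,
                "stratum": ["1A"] * 10,
            }
        )

    def test_totals_exclude_discards(self):
        table, report = tabulate_composition(self._results(), self._meta())
        assert table.totals.sum() == 8
        assert report["discarded"] == 2
        assert report["retained_fraction"] == pytest.approx(0.8)

    def test_empty_stratum_absent(self):
        table, _ = tabulate_composition(self._results(), self._meta())
        assert set(table.strata) == {"1A"}

    def test_missing_metadata_errors(self):
        meta = self._meta().iloc[:5]
        with pytest.raises(ValueError, match="metadata missing"):
            tabulate_composition(self._results(), meta)


class TestSelfAssignment:
    def test_dapc_at_least_as_good_as_bayes_on_separable(self):
        table, _ = synthdata.gen_baselines(
            n_pops=3, n_loci=50, fct=0.2, n_per_pop=25, seed=13
        )
        from codmix.assignment import allele_frequencies as af

        bf = af(table)
        model = dapc_fit(table)
        memb = dapc_predict(model, table)
        labels = np.array(table.group_labels)
        bayes_acc = np.mean(
            [
                bf.populations[np.argmax(bayes_assign(table.calls[i], bf))] == labels[i]
                for i in range(table.n_individuals)
            ]
        )
        dapc_acc = np.mean(
            [
                model.populations[np.argmax(memb[i])] == labels[i]
                for i in range(table.n_individuals)
            ]
        )
        assert dapc_acc >= 0.95 and bayes_acc >= 0.95

    def test_assign_all_consistency(self, baseline_pair):
        table, freqs = baseline_pair
        mixed, meta, _ = synthdata.gen_mixture_series(
            freqs, n_per_year=10, seed=17, sample_years=(2000, 2005)
        )
        results = assign_all(table, mixed, n_sim=200, seed=23)
        assert len(results) == mixed.n_individuals
        labelled = [r for r in results if r.consensus != DISCARDED]
        truth = meta.set_index("id")["true_origin"]
        acc = np.mean([truth[r.individual_id] == r.consensus for r in labelled])
        assert acc > 0.9
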