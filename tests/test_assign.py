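"""Assignment likelihoods, migrant detection and migration-rate matrices."""

import numpy as np
import pandas as pd
import pytest

from corridorgen import simdata
from corridorgen.assign import (assignment_scores, detect_migrants,
                                migrant_posterior, migration_matrices,
                                rm_log10_likelihood)
from corridorgen.genio import GenotypeTable
from corridorgen.popgen import allele_frequencies


def _table(genos_by_pop, n_loci=1):
    ids, pops, calls = [], [], []
    for pop, genos in genos_by_pop.items():
        for i, g in enumerate(genos):
            ids.append(f"{pop}{i}")
            pops.append(pop)
            calls.append([list(g)] * n_loci)
    return GenotypeTable(ids=ids, pops=pops,
                         loci=[f"L{i}" for i in range(n_loci)],
                         calls=np.array(calls))


class TestRmLikelihood:
    def test_sequential_draw_closed_form(self):
        # reference pop: 5 diploids all bb (n=10 copies); k=2 alleles across
        # pops; genotype aa: P = (0.5/11)*(1.5/12)
        t = _table({"ref": [(2, 2)] * 5, "other": [(1, 1)] * 2})
        fr = allele_frequencies(t)
        got = rm_log10_likelihood(np.array([[1, 1]]), fr, "ref")
        expect = np.log10((0.5 / 11) * (1.5 / 12))
        assert got == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(-2.2456, abs=5e-4)

    def test_unseen_allele_has_finite_likelihood(self):
        t = _table({"ref": [(2, 2)] * 5, "other": [(1, 3)] * 2})
        fr = allele_frequencies(t)
        assert np.isfinite(rm_log10_likelihood(np.array([[1, 3]]), fr, "ref"))

    def test_identical_reference_counts_give_identical_likelihood(self):
        t = _table({"A": [(1, 2), (2, 2)], "B": [(1, 2), (2, 2)],
                    "C": [(1, 1)] * 2})
        fr = allele_frequencies(t)
        g = np.array([[1, 2]])
        assert rm_log10_likelihood(g, fr, "A") == pytest.approx(
            rm_log10_likelihood(g, fr, "B"))

    def test_heterozygote_counts_both_orders(self):
        t = _table({"ref": [(1, 2)] * 4})
        fr = allele_frequencies(t)
        # P(het) = 2 * p1~ * p2~ under sequential draws
        n = 8.0
        k = 2
        p = 2 * ((4 + 1 / k) / (n + 1)) * ((4 + 1 / k) / (n + 2))
        got = rm_log10_likelihood(np.array([[1, 2]]), fr, "ref")
        assert got == pytest.approx(np.log10(p), abs=1e-12)


class TestLeaveOneOut:
    def test_own_alleles_do_not_inflate_home_likelihood(self):
        # one individual carries a private allele; with leave-one-out its
        # home score must not benefit from its own copies
        t = _table({"A": [(1, 1)] * 5 + [(9, 9)], "B": [(2, 2)] * 5}, n_loci=3)
        fr = allele_frequencies(t)
        loo = assignment_scores(t, leave_one_out=True)
        raw = assignment_scores(t, leave_one_out=False)
        assert loo.loc["A5", "A"] < raw.loc["A5", "A"]

    def test_non_home_scores_unchanged(self, two_pop_table):
        table, _, _ = two_pop_table
        loo = assignment_scores(table, leave_one_out=True)
        raw = assignment_scores(table, leave_one_out=False)
        for i, pop in enumerate(table.pops):
            other = [c for c in loo.columns if c != pop]
            assert np.allclose(loo.iloc[i][other], raw.iloc[i][other])


class TestDetectMigrants:
    def test_home_likeliest_gives_lambda_zero_and_no_flag(self, two_pop_table):
        table, _, _ = two_pop_table
        calls = detect_migrants(table, seed=0, n_sim=2000)
        best = calls[calls["assigned"] == calls["sampled"]]
        assert (best["lambda"] == 0).all()
        assert not best["flagged"].any()

    def test_lambda_nonnegative(self, two_pop_table):
        table, _, _ = two_pop_table
        calls = detect_migrants(table, seed=0, n_sim=2000)
        assert (calls["lambda"] >= 0).all()

    def test_planted_migrant_flagged(self, two_pop_table):
        table, freqs, _ = two_pop_table
        planted, truth = simdata.plant_migrants(table, freqs,
                                                [("pop1", "pop2")], seed=5)
        calls = detect_migrants(planted, seed=0)
        mid = truth.migrants[0]["id"]
        row = calls.set_index("id").loc[mid]
        assert row["flagged"] and row["assigned"] == "pop1"

    def test_lambda_invariant_to_unrelated_population_relabelling(
            self, two_pop_table):
        table, _, cfg = two_pop_table
        cfg3 = simdata.SimGenotypeConfig(n_pops=3, n_per_pop=(15, 15, 15),
                                         n_loci=14, n_alleles=10, F=0.15,
                                         seed=11)
        fr = simdata.sim_allele_freqs(cfg3)
        t3, _ = simdata.sim_genotypes(fr, cfg3)
        lam1 = detect_migrants(t3, seed=2, n_sim=1000).set_index("id")["lambda"]
        t3b = t3.copy()
        t3b.pops = [{"pop3": "zzz"}.get(p, p) for p in t3b.pops]
        lam2 = detect_migrants(t3b, seed=2, n_sim=1000).set_index("id")["lambda"]
        focal = [i for i, p in zip(t3.ids, t3.pops) if p != "pop3"]
        assert np.allclose(lam1.loc[focal], lam2.loc[focal])

    def test_single_population_rejected(self):
        t = _table({"A": [(1, 2)] * 5})
        with pytest.raises(ValueError):
            detect_migrants(t)


class TestMigrantPosterior:
    def test_nu_zero_collapses_to_resident(self, two_pop_table):
        table, _, _ = two_pop_table
        post = migrant_posterior(table, nu=0.0)
        assert np.allclose(post["p_resident"], 1.0)

    def test_identical_frequencies_posterior_equals_prior(self):
        t = _table({"A": [(1, 2), (1, 1), (2, 2)],
                    "B": [(1, 2), (1, 1), (2, 2)]}, n_loci=4)
        fr = allele_frequencies(t)
        post = migrant_posterior(t, nu=0.1, freqs=fr, leave_one_out=False)
        # likelihood identical under every hypothesis => posterior = prior
        assert np.allclose(post["p_resident"], 0.9, atol=1e-12)
        assert np.allclose(post["F0:B"].iloc[0], 0.05, atol=1e-12)

    def test_probabilities_sum_to_one(self, two_pop_table):
        table, _, _ = two_pop_table
        post = migrant_posterior(table, nu=0.05)
        cols = [c for c in post.columns
                if c == "p_resident" or c.startswith(("F0:", "F1:"))]
        assert np.allclose(post[cols].sum(axis=1), 1.0, atol=1e-9)

    def test_planted_migrants_get_high_probability(self, two_pop_table):
        table, freqs, _ = two_pop_table
        planted, truth = simdata.plant_migrants(table, freqs,
                                                [("pop1", "pop2")] * 3, seed=7)
        post = migrant_posterior(planted, nu=0.05).set_index("id")
        probs = [post.loc[m["id"], "migrant_probability"]
                 for m in truth.migrants]
        assert sum(p > 0.9 for p in probs) >= 2

    def test_invalid_nu_rejected(self, two_pop_table):
        table, _, _ = two_pop_table
        with pytest.raises(ValueError):
            migrant_posterior(table, nu=1.5)


class TestMigrationMatrices:
    def test_no_migrants_gives_identity(self):
        calls = pd.DataFrame({
            "id": ["a", "b"], "sampled": ["A", "B"], "assigned": ["A", "B"],
            "lambda": [0.0, 0.0], "p_resident": [1.0, 1.0],
            "flagged": [False, False]})
        rates = migration_matrices(calls)
        assert np.allclose(rates.matrix, np.eye(2))

    def test_one_in_five_assigned_away(self):
        calls = pd.DataFrame({
            "id": list("abcde"), "sampled": ["A"] * 5,
            "assigned": ["B", "A", "A", "A", "A"],
            "lambda": [3, 0, 0, 0, 0], "p_resident": [0.001, 1, 1, 1, 1],
            "flagged": [True, False, False, False, False]})
        calls = pd.concat([calls, pd.DataFrame({
            "id": ["x"], "sampled": ["B"], "assigned": ["B"], "lambda": [0.0],
            "p_resident": [1.0], "flagged": [False]})])
        rates = migration_matrices(calls)
        assert rates.to_frame().loc["A", "B"] == pytest.approx(0.2)

    def test_rows_sum_to_one(self, two_pop_table):
        table, _, _ = two_pop_table
        calls = detect_migrants(table, seed=1, n_sim=1000)
        rates = migration_matrices(calls)
        assert np.allclose(rates.matrix.sum(axis=1), 1.0, atol=1e-9)
        post = migrant_posterior(table, nu=0.05)
        rates2 = migration_matrices(post)
        assert np.allclose(rates2.matrix.sum(axis=1), 1.0, atol=1e-9)
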