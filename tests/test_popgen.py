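"""Diversity, P_ID-sibs, Weir–Cockerham theta, D_SP and ML relatedness."""

import numpy as np
import pytest

from corridorgen import simdata
from corridorgen.genio import GenotypeTable
from corridorgen.popgen import (allele_frequencies, diversity, dsp, fst_wc,
                                hwe_exact_mc, ml_relatedness, pid_sibs,
                                pairwise_dsp)


def _table(genos_by_pop, n_loci=1):
    """Build a table from {pop: [(a, b), ...]} single-locus genotypes."""
    ids, pops, calls = [], [], []
    for pop, genos in genos_by_pop.items():
        for i, g in enumerate(genos):
            ids.append(f"{pop}{i}")
            pops.append(pop)
            calls.append([list(g)] * n_loci)
    return GenotypeTable(ids=ids, pops=pops,
                         loci=[f"L{i}" for i in range(n_loci)],
                         calls=np.array(calls))


class TestAlleleFrequencies:
    def test_fixed_population(self):
        t = _table({"A": [(1, 1)] * 4})
        fr = allele_frequencies(t)
        assert fr.freqs[0][0].tolist() == [1.0]

    def test_even_split(self):
        t = _table({"A": [(1, 1)] * 5 + [(2, 2)] * 5})
        fr = allele_frequencies(t)
        assert np.allclose(fr.freqs[0][0], [0.5, 0.5])
        assert fr.n_copies[0, 0] == 20

    def test_recovers_generating_frequencies(self):
        cfg = simdata.SimGenotypeConfig(n_pops=1, n_per_pop=(400,), n_loci=1,
                                        n_alleles=4, F=0.0, seed=8)
        fr = simdata.sim_allele_freqs(cfg)
        table, _ = simdata.sim_genotypes(fr, cfg)
        est = allele_frequencies(table)
        se = np.sqrt(fr.freqs[0][0] * (1 - fr.freqs[0][0]) / 800)
        assert (np.abs(est.freqs[0][0] - fr.freqs[0][0]) < 4 * se + 1e-9).all()


class TestDiversity:
    def test_two_equifrequent_alleles(self):
        t = _table({"A": [(1, 2)] * 25 + [(1, 1)] * 13 + [(2, 2)] * 12})
        d = diversity(t, n_shuffles=200, seed=0)
        assert d["He"].iloc[0] == pytest.approx(0.5, abs=0.02)
        assert d["Al"].iloc[0] == 2

    def test_monomorphic_locus(self):
        t = _table({"A": [(1, 1)] * 10})
        d = diversity(t, seed=0)
        assert d["He"].iloc[0] == 0.0
        assert d["hwe_p"].iloc[0] == 1.0

    def test_hwe_not_rejected_at_hw_proportions(self):
        t = _table({"A": [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25})
        d = diversity(t, n_shuffles=2000, seed=1)
        assert d["hwe_p"].iloc[0] > 0.5

    def test_hwe_rejects_total_heterozygote_excess(self):
        t = _table({"A": [(1, 2)] * 50})
        d = diversity(t, n_shuffles=5000, seed=1)
        assert d["hwe_p"].iloc[0] < 0.001

    def test_hwe_pvalues_uniform_under_null(self):
        from scipy import stats
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            p = rng.dirichlet(np.ones(6))
            g = rng.choice(6, size=(100, 2), p=p)
            ps.append(hwe_exact_mc(g, n_shuffles=2000, rng=rng))
        assert stats.kstest(ps, "uniform").pvalue > 0.05


class TestPidSibs:
    def test_monomorphic_locus_gives_certainty(self):
        t = _table({"A": [(1, 1)] * 10})
        assert pid_sibs(allele_frequencies(t)) == pytest.approx(1.0)

    def test_biallelic_even_closed_form(self):
        t = _table({"A": [(1, 1)] * 5 + [(2, 2)] * 5})
        assert pid_sibs(allele_frequencies(t)) == pytest.approx(0.59375)

    def test_multiplicative_over_loci(self):
        t = _table({"A": [(1, 1)] * 5 + [(2, 2)] * 5}, n_loci=2)
        assert pid_sibs(allele_frequencies(t)) == pytest.approx(0.59375 ** 2)

    def test_adding_loci_never_increases_pid(self, two_pop_table):
        table, _, _ = two_pop_table
        fr = allele_frequencies(table)
        vals = [pid_sibs(fr, loci=fr.loci[:k]) for k in range(1, len(fr.loci))]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def _wc_oracle_one_locus(ns, ps, hs):
    """Literal Weir–Cockerham (1984) variance components for one allele."""
    r = len(ns)
    nbar = np.mean(ns)
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestFst:
    def test_fixed_differences_give_theta_one(self):
        t = _table({"A": [(1, 1)] * 10, "B": [(2, 2)] * 10}, n_loci=3)
        assert fst_wc(t, "A", "B").theta == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        cfg = simdata.SimGenotypeConfig(n_pops=2, n_per_pop=(100, 100),
                                        n_loci=14, n_alleles=8, F=0.0, seed=21)
        fr = simdata.sim_allele_freqs(cfg)
        table, _ = simdata.sim_genotypes(fr, cfg)
        assert abs(fst_wc(table, "pop1", "pop2").theta) < 0.02

    def test_matches_hand_computed_variance_components(self):
        # pop A: 10 AA; pop B: 5 AA + 5 aa
        t = _table({"A": [(1, 1)] * 10, "B": [(1, 1)] * 5 + [(2, 2)] * 5})
        res = fst_wc(t, "A", "B")
        comps = [_wc_oracle_one_locus([10, 10], ps, [0.0, 0.0])
                 for ps in ([1.0, 0.5], [0.0, 0.5])]  # per-allele freqs
        a = sum(x[0] for x in comps)
        b = sum(x[1] for x in comps)
        c = sum(x[2] for x in comps)
        assert res.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_symmetry_and_allele_relabelling(self):
        t = _table({"A": [(1, 2)] * 4 + [(1, 1)] * 4,
                    "B": [(2, 2)] * 5 + [(1, 2)] * 3})
        t2 = t.copy()
        t2.calls = np.where(t2.calls == 1, 7, t2.calls)  # relabel allele 1->7
        assert fst_wc(t, "A", "B").theta == pytest.approx(
            fst_wc(t, "B", "A").theta)
        assert fst_wc(t, "A", "B").theta == pytest.approx(
            fst_wc(t2, "A", "B").theta)

    def test_permutation_p_small_for_fixed_differences(self):
        t = _table({"A": [(1, 1)] * 8, "B": [(2, 2)] * 8}, n_loci=4)
        res = fst_wc(t, "A", "B", n_perm=99, seed=0)
        assert res.p_value <= 0.05

    def test_no_variation_flagged(self):
        t = _table({"A": [(1, 1)] * 5, "B": [(1, 1)] * 5})
        with pytest.raises(ValueError, match="no variation"):
            fst_wc(t, "A", "B")


class TestDsp:
    def test_identical_tables_share_everything(self):
        t = _table({"A": [(1, 2)] * 5, "B": [(1, 2)] * 5}, n_loci=3)
        v, se = dsp(t, "A", "B")
        assert v == pytest.approx(0.0)

    def test_half_shared_pair(self):
        t = _table({"A": [(1, 2)], "B": [(1, 3)]})
        v, _ = dsp(t, "A", "B", variant="one_minus")
        assert v == pytest.approx(0.5)

    def test_disjoint_alleles(self):
        t = _table({"A": [(1, 2)] * 3, "B": [(3, 4)] * 3})
        v, _ = dsp(t, "A", "B", variant="one_minus")
        assert v == pytest.approx(1.0)
        vlog, _ = dsp(t, "A", "B", variant="log")
        assert vlog == np.inf

    def test_log_variant_nonnegative_and_monotone(self, two_pop_table):
        table, _, _ = two_pop_table
        m = pairwise_dsp(table)
        off = m.values[np.triu_indices(2, 1)]
        assert (off >= 0).all()


class TestRelatedness:
    def test_identical_rare_genotypes_look_like_clones(self):
        rng = np.random.default_rng(0)
        calls = np.stack([rng.integers(1, 21, size=(14, 1)).repeat(2, axis=1)] * 2)
        filler = np.stack([np.stack([np.arange(1, 15), np.arange(1, 15)], 1)
                           for _ in range(18)])
        allcalls = np.concatenate([calls, filler + 20])
        t = GenotypeTable(ids=[f"s{i}" for i in range(20)], pops=["A"] * 20,
                          loci=[f"L{i}" for i in range(14)], calls=allcalls)
        est = ml_relatedness(t, ("s0", "s1"))
        assert est.r > 0.9
        assert est.k[2] > 0.85

    def test_unrelated_pairs_estimated_near_zero(self):
        # r-hat is constrained to [0, 1], so the null mean carries the usual
        # small positive boundary bias; with 14 informative loci it stays
        # small and the typical pair is called unrelated outright
        cfg = simdata.SimGenotypeConfig(n_pops=1, n_per_pop=(100,), n_loci=14,
                                        n_alleles=8, F=0.0, seed=13)
        fr = simdata.sim_allele_freqs(cfg)
        table, _ = simdata.sim_genotypes(fr, cfg)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(200):
            i, j = rng.choice(100, 2, replace=False)
            rs.append(ml_relatedness(table, (table.ids[i], table.ids[j]),
                                     freqs=fr).r)
        assert np.mean(rs) < 0.08
        assert np.median(rs) < 0.02

    def test_parent_offspring_category_recovered(self):
        cfg = simdata.SimGenotypeConfig(n_pops=1, n_per_pop=(250,), n_loci=14,
                                        n_alleles=10, F=0.0, seed=17)
        fr = simdata.sim_allele_freqs(cfg)
        table, _ = simdata.sim_genotypes(fr, cfg)
        rng = np.random.default_rng(2)
        hits = 0
        n_pairs = 100
        for p in range(n_pairs):
            parent = table.calls[p]
            child = np.empty_like(parent)
            for l in range(14):
                inherited = parent[l, rng.integers(2)]
                other = rng.choice(fr.alleles[l], p=fr.freqs[l][0])
                child[l] = sorted([inherited, other])
            table.calls[249 - p] = child  # overwrite an unrelated individual
            est = ml_relatedness(table, (table.ids[p], table.ids[249 - p]),
                                 freqs=fr)
            hits += est.category == "PO"
        assert hits > n_pairs / 2

    def test_k_on_simplex(self, two_pop_table):
        table, _, _ = two_pop_table
        est = ml_relatedness(table, (table.ids[0], table.ids[5]))
        assert est.k[0] >= 0 and est.k[1] >= 0 and est.k[2] >= 0
        assert sum(est.k) == pytest.approx(1.0)
        assert 0 <= est.r <= 1
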