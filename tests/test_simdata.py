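"""Synthetic-data generator: F-model, genotypes, replicates, landscapes."""

import numpy as np
import pytest

from corridorgen import simdata
from corridorgen.genio import MISSING
from corridorgen.popgen import _theta_from_components, _wc_components


class TestAlleleFreqs:
    def test_f_zero_gives_identical_populations(self):
        cfg = simdata.SimGenotypeConfig(F=0.0, seed=1)
        fr = simdata.sim_allele_freqs(cfg)
        for l in range(len(fr.loci)):
            assert np.allclose(fr.freqs[l], fr.freqs[l][0])

    def test_frequencies_normalized(self):
        fr = simdata.sim_allele_freqs(simdata.SimGenotypeConfig(seed=2))
        for l in range(len(fr.loci)):
            assert np.allclose(fr.freqs[l].sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_bit_identical(self):
        a = simdata.sim_allele_freqs(simdata.SimGenotypeConfig(seed=9))
        b = simdata.sim_allele_freqs(simdata.SimGenotypeConfig(seed=9))
        for l in range(len(a.loci)):
            assert np.array_equal(a.freqs[l], b.freqs[l])

    def test_f_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simdata.sim_allele_freqs(simdata.SimGenotypeConfig(F=1.0))

    @pytest.mark.parametrize("F", [0.05, 0.10, 0.20])
    def test_theta_recovers_generating_f(self, F):
        thetas = []
        for seed in range(20):
            cfg = simdata.SimGenotypeConfig(F=F, seed=seed, n_pops=6,
                                            n_per_pop=(50,) * 6, n_loci=14,
                                            n_alleles=10)
            fr = simdata.sim_allele_freqs(cfg)
            table, _ = simdata.sim_genotypes(fr, cfg)
            a, b, c = _wc_components(table, table.pop_names)
            thetas.append(_theta_from_components(a, b, c))
        thetas = np.asarray(thetas)
        assert abs(thetas.mean() - F) < 0.02
        assert abs(thetas.mean() - F) < 2 * thetas.std(ddof=1) / np.sqrt(20) + 0.01


class TestGenotypes:
    def test_fixed_allele_all_homozygous(self):
        cfg = simdata.SimGenotypeConfig(n_pops=1, n_per_pop=(20,), n_loci=1,
                                        n_alleles=2, F=0.0, seed=0)
        fr = simdata.sim_allele_freqs(cfg)
        fr.freqs[0][:] = [1.0, 0.0]
        table, _ = simdata.sim_genotypes(fr, cfg)
        assert (table.calls == 1).all()

    def test_no_missing_when_rate_zero(self):
        cfg = simdata.SimGenotypeConfig(seed=3, missing_rate=0.0)
        table, _ = simdata.sim_genotypes(simdata.sim_allele_freqs(cfg), cfg)
        assert (table.calls != MISSING).all()

    def test_missing_rate_applied(self):
        cfg = simdata.SimGenotypeConfig(seed=3, missing_rate=0.3)
        table, _ = simdata.sim_genotypes(simdata.sim_allele_freqs(cfg), cfg)
        frac = 1 - table.typed_mask().mean()
        assert 0.2 < frac < 0.4

    def test_heterozygosity_matches_binomial_expectation(self):
        cfg = simdata.SimGenotypeConfig(n_pops=1, n_per_pop=(200,), n_loci=1,
                                        n_alleles=2, F=0.0, seed=4)
        fr = simdata.sim_allele_freqs(cfg)
        fr.freqs[0][:] = [0.5, 0.5]
        table, _ = simdata.sim_genotypes(fr, cfg)
        ho = (table.calls[:, 0, 0] != table.calls[:, 0, 1]).mean()
        assert abs(ho - 0.5) < 0.07


class TestMigrants:
    def test_no_pairs_leaves_table_unchanged(self, two_pop_table):
        table, freqs, _ = two_pop_table
        out, truth = simdata.plant_migrants(table, freqs, [], seed=0)
        assert out.equals(table)
        assert truth.migrants == []

    def test_truth_records_source_and_label(self, two_pop_table):
        table, freqs, _ = two_pop_table
        out, truth = simdata.plant_migrants(table, freqs,
                                            [("pop1", "pop2")] * 2, seed=0)
        assert len(truth.migrants) == 2
        for m in truth.migrants:
            assert m["source"] == "pop1" and m["labelled"] == "pop2"
            assert m["source"] != m["labelled"]
            assert out.pops[out.ids.index(m["id"])] == "pop2"

    def test_overfull_destination_rejected(self, two_pop_table):
        table, freqs, _ = two_pop_table
        with pytest.raises(ValueError):
            simdata.plant_migrants(table, freqs, [("pop1", "pop2")], seed=0,
                                   n_per_pair=99)

    def test_truth_round_trips_through_json(self, tmp_path, two_pop_table):
        table, freqs, _ = two_pop_table
        _, truth = simdata.plant_migrants(table, freqs, [("pop1", "pop2")],
                                          seed=1)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = simdata.TruthRecord.from_json(p)
        assert back.migrants == truth.migrants


class TestReplicates:
    def test_error_free_replicates_identical(self, two_pop_table):
        table, _, _ = two_pop_table
        reps = simdata.sim_replicates(table, 0.0, 0.0, seed=0)
        for r in range(reps.n_reps):
            assert np.array_equal(reps.calls[:, :, r, :], table.calls)

    def test_full_dropout_makes_heterozygotes_homozygous(self, two_pop_table):
        table, _, _ = two_pop_table
        reps = simdata.sim_replicates(table, dropout_rate=1.0, seed=0)
        het = table.calls[:, :, 0] != table.calls[:, :, 1]
        rep_het = reps.calls[..., 0] != reps.calls[..., 1]
        assert not rep_het[het].any()

    def test_bad_rate_rejected(self, two_pop_table):
        table, _, _ = two_pop_table
        with pytest.raises(ValueError):
            simdata.sim_replicates(table, dropout_rate=1.5)


class TestLandscape:
    def test_no_settlements_means_dark_raster(self):
        cfg = simdata.SimLandscapeConfig(n_settlements=0, seed=0,
                                         barrier_spec=None)
        rasters, _ = simdata.sim_landscape(cfg)
        assert (rasters["lights"].data == 0).all()

    def test_tree_cover_range(self):
        rasters, _ = simdata.sim_landscape(simdata.SimLandscapeConfig(seed=1))
        tc = rasters["treecover"].data
        assert tc.min() >= 0 and tc.max() <= 67

    def test_grids_share_georeferencing(self):
        rasters, _ = simdata.sim_landscape(simdata.SimLandscapeConfig(seed=2))
        grids = [rasters[k] for k in ("landcover", "treecover", "lights")]
        assert len({g.shape for g in grids}) == 1
        assert len({g.cell_size_km for g in grids}) == 1

    def test_determinism(self):
        a, _ = simdata.sim_landscape(simdata.SimLandscapeConfig(seed=3))
        b, _ = simdata.sim_landscape(simdata.SimLandscapeConfig(seed=3))
        assert np.array_equal(a["lights"].data, b["lights"].data)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            simdata.sim_landscape(simdata.SimLandscapeConfig(shape=(5, 5)))

    def test_settlement_wall_raises_pair_resistance(self):
        from corridorgen import circuit
        from corridorgen.landscape import habitat_resistance, settlement_resistance

        def pair_R(barrier):
            cfg = simdata.SimLandscapeConfig(seed=6, n_patches=3,
                                             barrier_spec=barrier)
            rasters, truth = simdata.sim_landscape(cfg)
            layer, patches = habitat_resistance(rasters["landcover"])
            setl, _ = settlement_resistance(rasters["lights"])
            regions = {}
            for i, (x, y) in enumerate(truth.patch_centers):
                row, col = rasters["landcover"].cell_of(x, y)
                regions[f"p{i}"] = patches.labels == patches.labels[row, col]
            graph = circuit.build_graph(setl, regions=regions)
            solver = None
            return circuit.effective_resistance(graph, "p0", "p1")

        wall = {"wall_between": (0, 1), "value": 15.0, "width_cells": 4}
        assert pair_R(wall) > pair_R(None)


class TestGeneflow:
    def _freqs(self, n_pops=2, seed=0, F=0.3):
        cfg = simdata.SimGenotypeConfig(n_pops=n_pops,
                                        n_per_pop=(10,) * n_pops, n_loci=4,
                                        n_alleles=4, F=F, seed=seed)
        return simdata.sim_allele_freqs(cfg)

    def test_no_migration_no_drift_is_identity(self):
        fr = self._freqs()
        out = simdata.sim_geneflow_forward(fr, np.zeros((2, 2)), N_e=100,
                                           generations=25, drift=False)
        for l in range(len(fr.loci)):
            assert np.allclose(out.freqs[l], fr.freqs[l])

    def test_symmetric_half_mixing_equalizes_in_one_generation(self):
        fr = self._freqs()
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        out = simdata.sim_geneflow_forward(fr, m, N_e=100, generations=1,
                                           drift=False)
        for l in range(len(fr.loci)):
            assert np.allclose(out.freqs[l][0], out.freqs[l][1])

    def test_invalid_stochastic_matrix_rejected(self):
        fr = self._freqs()
        with pytest.raises(ValueError):
            simdata.sim_geneflow_forward(fr, np.array([[0.0, 1.2], [0.0, 0.0]]),
                                         N_e=100, generations=1)

    def test_drift_moves_frequencies_but_keeps_simplex(self):
        fr = self._freqs()
        out = simdata.sim_geneflow_forward(fr, np.zeros((2, 2)), N_e=50,
                                           generations=30, seed=1)
        for l in range(len(fr.loci)):
            assert np.allclose(out.freqs[l].sum(axis=1), 1.0)
        assert any(not np.allclose(out.freqs[l], fr.freqs[l])
                   for l in range(len(fr.loci)))
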