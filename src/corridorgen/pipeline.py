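"""Config-driven end-to-end orchestration with full provenance.

``run`` executes the whole chain on a simulated study system: landscape →
resistance layers → circuit-theory resistances between habitat patches →
landscape-coupled forward gene flow → genotypes with planted migrants →
replicate QC → diversity/differentiation → migrant detection → Mantel
tables.  Every stage draws from seeds derived from ``RunConfig.seed``, so a
rerun with the same config reproduces every table bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import corridorgen.assign as assign
import corridorgen.circuit as circuit
import corridorgen.genio as genio
import corridorgen.landscape as landscape
import corridorgen.popgen as popgen
import corridorgen.simdata as simdata
from corridorgen.mantel import ibd_test, rank_layers


@dataclass
class RunConfig:
    """All thresholds and simulation settings for one pipeline run.

    The QC and detection defaults are the conventional field settings:
    quality index cutoff 0.75, a 12-locus floor for identity, migrant
    detection at alpha 0.01 with 10000 simulated individuals, migration
    priors {0.01, 0.02, 0.05, 0.1}, habitat patches above 10 km², night
    lights above 20 treated as urban, and a 30 km habitat buffer.
    """

    seed: int = 0
    # simulation
    pop_sizes: tuple = simdata.DEFAULT_POP_SIZES
    n_loci: int = 14
    n_alleles: tuple = simdata.DEFAULT_ALLELE_COUNTS
    grid_shape: tuple = (60, 60)
    n_settlements: int = 25
    n_roads: int = 6
    barrier: dict | None = field(
        default_factory=lambda: {"ring_around_patch": 0, "value": 30.0,
                                 "width_cells": 4, "gap_deg": 35.0,
                                 "gap_value": 15.0})
    generations: int = 200
    N_e: float = 100.0
    m0: float = 0.02
    migrant_pairs: tuple = (("pop5", "pop4"), ("pop5", "pop4"),
                            ("pop6", "pop2"), ("pop4", "pop1"))
    # replicate QC
    n_reps: int = 4
    dropout_rate: float = 0.05
    false_allele_rate: float = 0.01
    qi_threshold: float = 0.75
    min_loci: int = 12
    # migrant detection
    alpha: float = 0.01
    n_sim: int = 10000
    migprior: tuple = (0.01, 0.02, 0.05, 0.1)
    # landscape thresholds
    min_patch_km2: float = 10.0
    urban_threshold: float = 20.0
    buffer_km: float = 30.0
    # mantel
    n_perm: int = 9999

    def validate(self) -> None:
        if not (0 < self.qi_threshold <= 1):
            raise ValueError("qi_threshold must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_patch_km2 < 0 or self.buffer_km <= 0:
            raise ValueError("invalid landscape thresholds")
        if any(not (0 <= nu < 1) for nu in self.migprior):
            raise ValueError("migration priors must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("pop_sizes", "n_alleles", "grid_shape", "migprior"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "migrant_pairs" in d:
            d["migrant_pairs"] = tuple(tuple(p) for p in d["migrant_pairs"])
        return cls(**d)


@dataclass
class RunReport:
    """All tables a run produces, plus a provenance log."""

    config: RunConfig
    diversity: pd.DataFrame
    fst: pd.DataFrame
    fst_se: pd.DataFrame
    dsp: pd.DataFrame
    dsp_se: pd.DataFrame
    migrants: pd.DataFrame
    migration: pd.DataFrame
    resistance: dict[str, pd.DataFrame]
    mantel_distance: pd.DataFrame
    mantel_dsp: pd.DataFrame
    mantel_emigration: pd.DataFrame
    mantel_immigration: pd.DataFrame
    qc: pd.DataFrame
    truth: simdata.TruthRecord
    log: list[str]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# corridorgen run, seed={self.config.seed}\n"
        for name in ("diversity", "fst", "fst_se", "dsp", "dsp_se",
                     "migrants", "migration", "mantel_distance",
                     "mantel_dsp", "mantel_emigration",
                     "mantel_immigration", "qc"):
            df = getattr(self, name)
            with open(out / f"{name}.csv", "w") as fh:
                fh.write(header)
                df.to_csv(fh)
        for lname, df in self.resistance.items():
            with open(out / f"resistance_{lname}.csv", "w") as fh:
                fh.write(header)
                df.to_csv(fh)
        self.truth.to_json(out / "truth.json")
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, default=str)


LAYER_COMBOS = [
    ("settlements",), ("habitat",), ("treecover",), ("roads",),
    ("settlements", "roads"), ("settlements", "habitat"),
    ("settlements", "treecover"), ("roads", "habitat"),
    ("roads", "treecover"), ("treecover", "habitat"),
    ("settlements", "roads", "treecover"),
    ("settlements", "roads", "habitat"),
    ("settlements", "treecover", "habitat"),
    ("roads", "treecover", "habitat"),
    ("settlements", "roads", "treecover", "habitat"),
]


def simulate_study_system(config: RunConfig):
    """Landscape, resistance layers, circuit resistances and genotypes.

    Gene flow follows the settlement surface: migration between patches is
    m_ij = m0·exp(−R_ij/τ) with R from the settlement resistance layer, so
    a settlement barrier around a patch suppresses its gene flow.  Returns
    (genotype table, frequency table, layers dict, resistance matrices dict,
    region coordinates, truth, log).
    """
    config.validate()
    log: list[str] = []
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8)
    n_pops = len(config.pop_sizes)

    lcfg = simdata.SimLandscapeConfig(
        shape=tuple(config.grid_shape), n_patches=n_pops,
        n_settlements=config.n_settlements, n_roads=config.n_roads,
        barrier_spec=config.barrier, seed=int(seeds[0]))
    rasters, truth = simdata.sim_landscape(lcfg)
    landcover = rasters["landcover"]

    hab_layer, patches = landscape.habitat_resistance(
        landcover, habitat_classes=(1,), min_patch_km2=config.min_patch_km2)
    set_layer, urban = landscape.settlement_resistance(
        rasters["lights"], urban_threshold=config.urban_threshold)
    tc_layer = landscape.treecover_resistance(rasters["treecover"])
    rd_layer = landscape.road_resistance(rasters["roads"], landcover)
    valid = landscape.study_area(patches, landcover,
                                 buffer_km=config.buffer_km, urban_mask=urban)
    layers = {
        "habitat": landscape.apply_mask(hab_layer, valid),
        "settlements": landscape.apply_mask(set_layer, valid),
        "treecover": landscape.apply_mask(tc_layer, valid),
        "roads": landscape.apply_mask(rd_layer, valid),
    }
    log.append(f"landscape: {patches.n_patches} patches "
               f"(areas {sorted(patches.areas_km2.values())}), "
               f"{int(urban.sum())} urban cells masked")

    # regions: the patch containing each simulated patch centre
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    regions: dict[str, np.ndarray] = {}
    coords = []
    for i, (x, y) in enumerate(truth.patch_centers[:n_pops]):
        row, col = landcover.cell_of(x, y)
        pid = patches.labels[row, col]
        if pid == 0:
            raise RuntimeError("patch centre fell outside a retained patch")
        regions[pops[i]] = patches.labels == pid
        coords.append((x, y))
    coords = np.asarray(coords)

    resist: dict[str, pd.DataFrame] = {}
    for names in LAYER_COMBOS:
        combo = (layers[names[0]] if len(names) == 1
                 else landscape.combine_layers([layers[n] for n in names]))
        graph = circuit.build_graph(combo, neighbourhood=8, regions=regions)
        res = circuit.pairwise_resistance(graph)
        key = "+".join(names)
        resist[key] = pd.DataFrame(res.resistance, index=pops, columns=pops)
        if np.isinf(res.resistance).any():
            log.append(f"warning: disconnected pair(s) in layer {key}")

    # gene flow from the settlement surface
    R = resist["settlements"].to_numpy()
    m = simdata.migration_from_resistance(R, m0=config.m0)
    truth.migration_matrix = m.tolist()
    gcfg = simdata.SimGenotypeConfig(
        n_pops=n_pops, n_per_pop=tuple(config.pop_sizes),
        n_loci=config.n_loci, n_alleles=config.n_alleles, F=0.0,
        seed=int(seeds[1]))
    freqs0 = simdata.sim_allele_freqs(gcfg)
    freqs = simdata.sim_geneflow_forward(freqs0, m, N_e=config.N_e,
                                         generations=config.generations,
                                         seed=int(seeds[2]))
    table, gtruth = simdata.sim_genotypes(freqs, gcfg)
    truth.generating_F = None
    truth.seeds.update(gtruth.seeds)
    table.coords = np.array([coords[pops.index(p)] for p in table.pops])
    if config.migrant_pairs:
        table, truth = simdata.plant_migrants(
            table, freqs, list(config.migrant_pairs), seed=int(seeds[3]),
            truth=truth)
        log.append(f"planted {len(truth.migrants)} migrants")
    return table, freqs, layers, resist, coords, truth, log, seeds


def run(config: RunConfig | None = None) -> RunReport:
    """Execute the full pipeline on a simulated study system."""
    config = config or RunConfig()
    t0 = time.time()
    (table, freqs, layers, resist, coords, truth, log, seeds
     ) = simulate_study_system(config)

    # replicate QC
    reps = simdata.sim_replicates(table, dropout_rate=config.dropout_rate,
                                  false_allele_rate=config.false_allele_rate,
                                  n_reps=config.n_reps, seed=int(seeds[4]))
    cons = genio.consensus_genotypes(reps, qi_threshold=config.qi_threshold,
                                     min_loci=config.min_loci)
    qc = pd.DataFrame({"id": cons.table.ids,
                       "quality_index": cons.quality_index,
                       "retained": cons.retained}).set_index("id")
    kept = cons.retained_table()
    kept.coords = table.coords[np.flatnonzero(cons.retained)]
    uniq, dup_map, dropped = genio.identify_individuals(
        kept, min_loci=config.min_loci)
    uniq.coords = kept.coords[[kept.ids.index(i) for i in uniq.ids]]
    log.append(f"QC: {int(cons.retained.sum())}/{len(cons.retained)} samples "
               f"retained, {len(dup_map)} duplicate groups, "
               f"{len(dropped)} dropped below {config.min_loci} loci")
    small = [p for p in uniq.pop_names if len(uniq.pop_indices(p)) < 3]
    if small:
        log.append(f"warning: populations with <3 individuals: {small}")

    # diversity and differentiation
    div = popgen.diversity(uniq, seed=int(seeds[5]))
    fst = popgen.pairwise_fst(uniq)
    dspm = popgen.pairwise_dsp(uniq)

    # migrants
    mig = assign.detect_migrants(uniq, alpha=config.alpha,
                                 n_sim=config.n_sim, seed=int(seeds[6]))
    for nu in config.migprior:
        post = assign.migrant_posterior(uniq, nu=nu)
        mig[f"migrant_prob_nu{nu:g}"] = post["migrant_probability"].to_numpy()
    rates = assign.migration_matrices(mig, pops=uniq.pop_names)

    # Mantel tables
    pops = uniq.pop_names
    def df2mat(df):
        return df.loc[pops, pops].to_numpy()

    gen_mats = {
        "F_ST": fst.to_frame().pipe(df2mat),
        "D_SP": dspm.to_frame().pipe(df2mat),
        "immigration": _rate_distance(rates.to_frame().pipe(df2mat), "col"),
        "emigration": _rate_distance(rates.to_frame().pipe(df2mat), "row"),
    }
    pop_coords = np.asarray(
        [uniq.coords[uniq.pop_indices(p)].mean(axis=0) for p in pops])
    rows = []
    for name, G in gen_mats.items():
        res = ibd_test(G, pop_coords, n_perm=config.n_perm,
                       seed=int(seeds[7]))
        rows.append((name, res.r, res.r2, res.p))
    mantel_distance = pd.DataFrame(rows, columns=["statistic", "r", "r2", "p"])

    layer_mats = {k: v.to_numpy() for k, v in resist.items()}
    mantel_dsp = rank_layers(gen_mats["D_SP"], layer_mats,
                                    n_perm=config.n_perm, seed=int(seeds[7]))
    mantel_emi = rank_layers(gen_mats["emigration"], layer_mats,
                                    n_perm=config.n_perm, seed=int(seeds[7]))
    mantel_imm = rank_layers(gen_mats["immigration"], layer_mats,
                                    n_perm=config.n_perm, seed=int(seeds[7]))
    log.append(f"run completed in {time.time() - t0:.1f} s")
    return RunReport(
        config=config, diversity=div,
        fst=fst.to_frame(), fst_se=fst.se_frame(),
        dsp=dspm.to_frame(), dsp_se=dspm.se_frame(),
        migrants=mig, migration=rates.to_frame(), resistance=resist,
        mantel_distance=mantel_distance, mantel_dsp=mantel_dsp,
        mantel_emigration=mantel_emi, mantel_immigration=mantel_imm,
        qc=qc, truth=truth, log=log)


def _rate_distance(m: np.ndarray, axis: str) -> np.ndarray:
    """Asymmetric dissimilarity from a migration-rate matrix.

    Rates measure connectivity (higher = closer); tests use 1 − rate so the
    matrix is oriented like a distance.  ``axis='row'`` keeps emigration
    orientation m[i, j], ``'col'`` transposes to immigration orientation.
    """
    off = m.copy().astype(float)
    np.fill_diagonal(off, 0.0)
    d = 1.0 - off
    np.fill_diagonal(d, 0.0)
    return d if axis == "row" else d.T


def make_fixture(seed: int = 0, outdir=None):
    """Small bundled study system: six populations of sizes (5,7,5,16,15,7),
    14 loci, planted migrants over several population pairs, and a 60×60
    landscape with a settlement barrier.

    Returns (GenotypeTable, AlleleFrequencyTable, layers, resistance dict,
    TruthRecord); with ``outdir`` also writes Genepop, ASCII grids and
    truth JSON.
    """
    config = RunConfig(seed=seed)
    table, freqs, layers, resist, coords, truth, log, _ = \
        simulate_study_system(config)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        genio.write_genepop(table, out / "genotypes.gen")
        for name, layer in layers.items():
            landscape.write_ascii_grid(layer.raster, out / f"{name}.asc")
        truth.to_json(out / "truth.json")
        for key, df in resist.items():
            df.to_csv(out / f"resistance_{key.replace('+', '_')}.csv")
    return table, freqs, layers, resist, truth
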