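"""Synthetic genotypes, replicate calls, migrants and landscapes.

The generator emulates a six-population microsatellite study: an F-model
(correlated Dirichlet) produces population allele frequencies whose
expected Weir–Cockerham theta equals the divergence parameter F; diploid
genotypes are drawn under Hardy–Weinberg within populations; first-
generation migrants are planted by drawing an individual from the source
population's frequencies and labelling it with the destination.  Landscape
rasters (habitat classes, percent tree cover, night-light radiance) and
road polylines are generated with known ground truth, including an optional
settlement barrier, and a forward migration–drift process couples gene flow
to landscape resistance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from corridorgen.genio import MISSING, GenotypeTable, ReplicateSet
from corridorgen.landscape import RasterGrid
from corridorgen.popgen import AlleleFrequencyTable

# Default per-locus allele counts: 14 loci spanning 5-16 alleles with a
# mean of 11.71, the richness typical of felid microsatellite panels.
DEFAULT_ALLELE_COUNTS = (5, 7, 8, 9, 10, 11, 12, 13, 13, 14, 15, 15, 16, 16)
DEFAULT_POP_SIZES = (5, 7, 5, 16, 15, 7)


@dataclass
class SimGenotypeConfig:
    """Study design for the genotype simulator.

    ``F`` is the divergence of each population from the shared ancestral
    frequency pool, on the F_ST scale; the default 0.12 sits inside the
    0.03–0.22 range typical of fragmented large-carnivore populations.
    """

    n_pops: int = 6
    n_per_pop: Sequence[int] = DEFAULT_POP_SIZES
    n_loci: int = 14
    n_alleles: int | Sequence[int] = DEFAULT_ALLELE_COUNTS
    F: float = 0.12
    missing_rate: float = 0.0
    seed: int = 0

    def allele_counts(self) -> list[int]:
        if np.isscalar(self.n_alleles):
            return [int(self.n_alleles)] * self.n_loci
        counts = list(self.n_alleles)
        if len(counts) != self.n_loci:
            raise ValueError("n_alleles list must match n_loci")
        return [int(c) for c in counts]

    def validate(self) -> None:
        if not (0 <= self.F < 1):
            raise ValueError("F must lie in [0, 1)")
        if any(c < 2 for c in self.allele_counts()):
            raise ValueError("every locus needs >= 2 alleles")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must lie in [0, 1]")
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop must have n_pops entries")


@dataclass
class SimLandscapeConfig:
    """Synthetic landscape: habitat blobs, settlements, roads, tree cover."""

    shape: tuple[int, int] = (60, 60)
    cell_size_km: float = 1.0
    n_patches: int = 6
    n_settlements: int = 25
    n_roads: int = 6
    barrier_spec: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.shape[0] < 10 or self.shape[1] < 10:
            raise ValueError("grid must be at least 10x10")


@dataclass
class TruthRecord:
    """Ground truth carried alongside simulated data."""

    migrants: list[dict] = field(default_factory=list)  # {id, source, labelled}
    generating_F: float | None = None
    patch_centers: list[tuple[float, float]] = field(default_factory=list)
    settlement_cells: list[tuple[int, int]] = field(default_factory=list)
    roads: list[list[tuple[float, float]]] = field(default_factory=list)
    migration_matrix: list[list[float]] | None = None
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        tr = cls()
        for k, v in d.items():
            setattr(tr, k, v)
        tr.migrants = [dict(m) for m in tr.migrants]
        return tr


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes


def sim_allele_freqs(config: SimGenotypeConfig) -> AlleleFrequencyTable:
    """Draw per-population allele frequencies under the F-model.

    Ancestral frequencies come from a flat Dirichlet; each population's
    frequencies from Dirichlet(p_ancestral · (1−F)/F), so that the expected
    among-population variance matches F on the F_ST scale.  F = 0 returns
    the ancestral frequencies for every population.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.allele_counts()
    pops = [f"pop{i + 1}" for i in range(config.n_pops)]
    loci = [f"loc{l + 1}" for l in range(config.n_loci)]
    freqs = []
    alleles = []
    for k in counts:
        anc = rng.dirichlet(np.ones(k))
        if config.F == 0:
            f = np.tile(anc, (config.n_pops, 1))
        else:
            conc = anc * (1 - config.F) / config.F
            f = rng.dirichlet(conc, size=config.n_pops)
        freqs.append(f)
        alleles.append(np.arange(1, k + 1))
    n_copies = np.tile(2.0 * np.asarray(config.n_per_pop)[:, None],
                       (1, config.n_loci))
    return AlleleFrequencyTable(pops=pops, loci=loci, alleles=alleles,
                                freqs=freqs, n_copies=n_copies)


def sim_genotypes(freqs: AlleleFrequencyTable, config: SimGenotypeConfig
                  ) -> tuple[GenotypeTable, TruthRecord]:
    """Draw diploid genotypes under Hardy–Weinberg within populations."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids: list[str] = []
    pops: list[str] = []
    L = len(freqs.loci)
    rows = []
    for pi, pop in enumerate(freqs.pops):
        for j in range(config.n_per_pop[pi]):
            ids.append(f"{pop}_i{j + 1}")
            pops.append(pop)
            row = np.empty((L, 2), dtype=np.int64)
            for l in range(L):
                p = freqs.freqs[l][pi]
                row[l] = rng.choice(freqs.alleles[l], size=2, p=p)
            rows.append(row)
    calls = np.stack(rows) if rows else np.empty((0, L, 2), np.int64)
    if config.missing_rate > 0:
        miss = rng.random((len(ids), L)) < config.missing_rate
        calls[miss] = MISSING
    table = GenotypeTable(ids=ids, pops=pops, loci=list(freqs.loci), calls=calls)
    truth = TruthRecord(generating_F=config.F, seeds={"genotypes": config.seed})
    return table, truth


def plant_migrants(table: GenotypeTable, freqs: AlleleFrequencyTable,
                   pairs: Sequence[tuple[str, str]], seed: int = 0,
                   truth: TruthRecord | None = None,
                   n_per_pair: int = 1) -> tuple[GenotypeTable, TruthRecord]:
    """Plant first-generation migrants by genotype replacement.

    For each (source, destination) pair, ``n_per_pair`` individuals sampled
    in the destination have their genotype replaced by a fresh draw from the
    *source* population's allele frequencies; the population label stays the
    destination, which is exactly an F0 migrant.  Truth records the planted
    ids.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    truth = truth or TruthRecord()
    taken: set[int] = set()
    for src, dst in pairs:
        if src not in freqs.pops or dst not in table.pop_names:
            raise ValueError(f"unknown population in pair ({src}, {dst})")
        cand = [i for i in table.pop_indices(dst) if i not in taken]
        if n_per_pair > len(cand):
            raise ValueError(f"not enough individuals in {dst} to plant migrants")
        chosen = rng.choice(cand, size=n_per_pair, replace=False)
        pi = freqs.pop_index(src)
        for i in chosen:
            taken.add(int(i))
            for l in range(len(freqs.loci)):
                p = freqs.freqs[l][pi]
                out.calls[i, l] = np.sort(rng.choice(freqs.alleles[l], size=2, p=p))
            truth.migrants.append({"id": out.ids[i], "source": src,
                                   "labelled": dst})
    truth.seeds["migrants"] = seed
    return out, truth


def sim_replicates(table: GenotypeTable, dropout_rate: float = 0.0,
                   false_allele_rate: float = 0.0, n_reps: int = 4,
                   seed: int = 0) -> ReplicateSet:
    """Replicate amplifications with allelic dropout and false alleles.

    Per replicate call, a heterozygote loses one allele (appearing
    homozygous) with ``dropout_rate``; independently, each allele copy is
    replaced by a random *different* allele from the locus's observed set
    with ``false_allele_rate``.
    """
    for r in (dropout_rate, false_allele_rate):
        if not (0 <= r <= 1):
            raise ValueError("error rates must lie in [0, 1]")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    n, L, _ = table.calls.shape
    reps = np.repeat(table.calls[:, :, None, :], n_reps, axis=2)
    allele_sets = [table.alleles_at(l) for l in range(L)]
    for i in range(n):
        for l in range(L):
            a, b = table.calls[i, l]
            if a == MISSING:
                continue
            for r in range(n_reps):
                call = [a, b]
                if a != b and rng.random() < dropout_rate:
                    keep = call[rng.integers(2)]
                    call = [keep, keep]
                for s in range(2):
                    if rng.random() < false_allele_rate:
                        others = allele_sets[l][allele_sets[l] != call[s]]
                        if others.size:
                            call[s] = int(rng.choice(others))
                reps[i, l, r] = sorted(call)
    return ReplicateSet(ids=list(table.ids), pops=list(table.pops),
                        loci=list(table.loci), calls=reps)


# ---------------------------------------------------------------------------
# Landscape


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    z = ndimage.gaussian_filter(z, sigma=sigma)
    z -= z.min()
    if z.max() > 0:
        z /= z.max()
    return z


def sim_landscape(config: SimLandscapeConfig
                  ) -> tuple[dict[str, object], TruthRecord]:
    """Generate co-registered landscape inputs with ground truth.

    Returns a dict with ``landcover`` (class raster: 1 = forest habitat,
    0 = other), ``treecover`` (percent, 0–67), ``lights`` (night-light
    radiance with settlements; values > 20 mark urban centres), ``roads``
    (list of polylines in km coordinates), plus a TruthRecord with patch
    centres, settlement cells and road vertices.

    ``barrier_spec`` may be ``{"ring_around_patch": i, "radius_km": r,
    "value": v}`` (settlement ring enclosing patch i) or ``{"wall_between":
    (i, j), "value": v}`` (settlement band across the midline of two
    patches).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nr, nc = config.shape
    cs = config.cell_size_km
    truth = TruthRecord(seeds={"landscape": config.seed})

    # habitat patches: blobs around well-separated centres
    margin = 0.15
    centers: list[tuple[float, float]] = []
    sep = 0.30 * min(nr, nc)
    while len(centers) < config.n_patches:
        placed = False
        for _ in range(500):
            r = rng.uniform(margin * nr, (1 - margin) * nr)
            c = rng.uniform(margin * nc, (1 - margin) * nc)
            if all(np.hypot(r - r0, c - c0) > sep for r0, c0 in centers):
                centers.append((r, c))
                placed = True
                break
        if not placed:
            sep *= 0.9  # relax separation until all patches fit
    rr, cc = np.mgrid[0:nr, 0:nc]
    habitat = np.zeros((nr, nc), dtype=bool)
    radius = 0.08 * min(nr, nc)
    for (r0, c0) in centers:
        habitat |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    landcover = habitat.astype(float)
    truth.patch_centers = [(float(c0 * cs), float((nr - r0) * cs))
                           for r0, c0 in centers]

    # tree cover: smooth gradient, boosted inside habitat, clipped to 0-67
    tc = _smooth_noise(rng, (nr, nc), sigma=6.0) * 45
    tc[habitat] += 22
    treecover = np.clip(tc, 0, 67)

    # settlements: point sources with exponential kernels; avoid habitat
    lights = np.zeros((nr, nc))
    settle_cells = []
    for _ in range(config.n_settlements):
        for _try in range(200):
            r0 = rng.integers(0, nr)
            c0 = rng.integers(0, nc)
            if not habitat[r0, c0]:
                break
        peak = rng.uniform(3, 40)
        d = np.hypot(rr - r0, cc - c0)
        lights += peak * np.exp(-d / 1.2)
        settle_cells.append((int(r0), int(c0)))
    lights[lights < 0.5] = 0.0
    truth.settlement_cells = settle_cells

    # barrier
    spec = config.barrier_spec or {}
    if "ring_around_patch" in spec:
        # settlement ring enclosing one patch: lit but sub-urban cells, so
        # the wall raises the settlement-proximity resistance around that
        # population without removing cells from the landscape (the barrier
        # lives only in the settlement layer).  An optional gap (degrees,
        # facing the grid centre) can breach the ring; with "value" above
        # the urban threshold the ring becomes an absolute urban barrier.
        pi = spec["ring_around_patch"]
        rad = spec.get("radius_km", 2.0 * radius * cs) / cs
        width = spec.get("width_cells", 4)
        val = spec.get("value", 15.0)
        gap_deg = spec.get("gap_deg", 0.0)
        gap_val = spec.get("gap_value", 15.0)
        r0, c0 = centers[pi]
        d = np.hypot(rr - r0, cc - c0)
        ring = (d >= rad) & (d < rad + width)
        lights[ring] = np.maximum(lights[ring], val)
        if gap_deg > 0:
            ang = np.degrees(np.arctan2(rr - r0, cc - c0))
            gap_dir = float(np.degrees(np.arctan2(nr / 2 - r0, nc / 2 - c0)))
            gap = ring & (np.abs(((ang - gap_dir + 180) % 360) - 180)
                          < gap_deg / 2)
            lights[gap] = gap_val
        truth.settlement_cells += [(int(a), int(b)) for a, b in zip(*np.where(ring))]
    elif "wall_between" in spec:
        i, j = spec["wall_between"]
        val = spec.get("value", 15.0)
        width = spec.get("width_cells", 2)
        (r1, c1), (r2, c2) = centers[i], centers[j]
        # band through the midpoint, perpendicular to the patch axis
        mr, mc = (r1 + r2) / 2, (c1 + c2) / 2
        ur, uc = r2 - r1, c2 - c1
        norm = np.hypot(ur, uc)
        ur, uc = ur / norm, uc / norm
        proj = (rr - mr) * ur + (cc - mc) * uc
        band = np.abs(proj) < width / 2 + 0.5
        lights[band] = np.maximum(lights[band], val)
        truth.settlement_cells += [(int(a), int(b)) for a, b in zip(*np.where(band))]

    # roads: highways spanning the grid border to border (with a jittered
    # interior waypoint), so crossing them is unavoidable for some pairs
    def border_point():
        side = rng.integers(4)
        if side == 0:
            return (0.0, rng.uniform(0, nr * cs))
        if side == 1:
            return (nc * cs, rng.uniform(0, nr * cs))
        if side == 2:
            return (rng.uniform(0, nc * cs), 0.0)
        return (rng.uniform(0, nc * cs), nr * cs)

    roads = []
    for _ in range(config.n_roads):
        p0 = border_point()
        p2 = border_point()
        while np.hypot(p2[0] - p0[0], p2[1] - p0[1]) < 0.5 * min(nr, nc) * cs:
            p2 = border_point()
        p1 = (rng.uniform(0.25, 0.75) * nc * cs,
              rng.uniform(0.25, 0.75) * nr * cs)
        roads.append([p0, p1, p2])
    truth.roads = roads

    origin = (0.0, 0.0)
    mk = lambda v: RasterGrid(data=np.asarray(v, dtype=float),
                              cell_size_km=cs, origin=origin, nodata=-9999.0)
    layers = {
        "landcover": mk(landcover),
        "treecover": mk(treecover),
        "lights": mk(lights),
        "roads": roads,
    }
    return layers, truth


# ---------------------------------------------------------------------------
# Forward migration-drift


def sim_geneflow_forward(freqs0: AlleleFrequencyTable,
                         migration_matrix: np.ndarray, N_e: float,
                         generations: int, seed: int = 0,
                         drift: bool = True) -> AlleleFrequencyTable:
    """Forward-time migration plus drift on allele frequencies.

    Per generation, deterministic mixing
    p_i <- (1 − Σ_{j≠i} m_ij) p_i + Σ_{j≠i} m_ij p_j followed (if ``drift``)
    by multinomial resampling of 2·N_e gene copies per population.
    """
    m = np.asarray(migration_matrix, dtype=float)
    n = len(freqs0.pops)
    if m.shape != (n, n):
        raise ValueError("migration matrix shape mismatch")
    if (m < 0).any():
        raise ValueError("negative migration rates")
    off = m.copy()
    np.fill_diagonal(off, 0.0)
    if (off.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("off-diagonal row sums must be <= 1")
    if drift and N_e < 10:
        raise ValueError("N_e must be >= 10")
    rng = np.random.default_rng(seed)
    M = off.copy()
    np.fill_diagonal(M, 1.0 - off.sum(axis=1))
    out_freqs = []
    for l in range(len(freqs0.loci)):
        p = freqs0.freqs[l].copy()
        for _ in range(generations):
            p = M @ p
            if drift:
                ncop = int(round(2 * N_e))
                for i in range(n):
                    p[i] = rng.multinomial(ncop, p[i] / p[i].sum()) / ncop
        out_freqs.append(p)
    return AlleleFrequencyTable(pops=list(freqs0.pops), loci=list(freqs0.loci),
                                alleles=[a.copy() for a in freqs0.alleles],
                                freqs=out_freqs,
                                n_copies=freqs0.n_copies.copy())


def migration_from_resistance(R: np.ndarray, m0: float = 0.02,
                              tau: float | None = None) -> np.ndarray:
    """Turn a pairwise resistance matrix into a migration matrix.

    m_ij = m0 · exp(−R_ij / τ) for i ≠ j, with τ defaulting to half the
    mean finite off-diagonal resistance; rows are scaled down if the total
    emigration exceeds 0.5 so the matrix stays stochastic.  With N_e = 100
    the defaults put well-connected population pairs near the drift-
    migration balance F_ST ≈ 1/(4·N_e·m_tot + 1) ≈ 0.04 and a walled-off
    population near 0.2.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(R)
    if tau is None:
        tau = float(R[finite].mean()) / 2.0 if finite.any() else 1.0
    m = np.zeros_like(R)
    m[finite] = m0 * np.exp(-R[finite] / tau)
    rows = m.sum(axis=1)
    scale = np.where(rows > 0.5, 0.5 / np.maximum(rows, 1e-12), 1.0)
    m *= scale[:, None]
    return m
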