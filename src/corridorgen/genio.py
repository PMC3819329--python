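"""Genotype data model, Genepop/CSV I/O, replicate consensus and identity.

The central container is :class:`GenotypeTable`: individuals x loci diploid
allele calls with population labels and optional coordinates.  Allele calls
are stored as integer allele codes (the sizes written in a Genepop file);
missing calls are ``-1`` in both slots.  Unordered pairs are kept sorted
ascending so genotype comparison is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for a set of individuals.

    Parameters
    ----------
    ids : list of str
        Sample / individual identifiers, unique.
    pops : list of str
        Population label per individual (sampling location).
    loci : list of str
        Locus names.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Allele codes; ``-1`` marks a missing allele.  Pairs are sorted
        ascending with missing values last.
    coords : ndarray of float, shape (n_individuals, 2), optional
        x/y coordinates (km) of the sampling point.
    """

    ids: list[str]
    pops: list[str]
    loci: list[str]
    calls: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.ids)}, {len(self.loci)}, 2)"
            )
        if len(self.pops) != len(self.ids):
            raise ValueError("pops and ids must have equal length")
        self.calls = _canonical_pairs(self.calls)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_names(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pops, dtype=object) == pop)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): call present at locus."""
        return (self.calls != MISSING).all(axis=2)

    def typed_loci_count(self) -> np.ndarray:
        return self.typed_mask().sum(axis=1)

    def alleles_at(self, locus: int) -> np.ndarray:
        """Sorted unique allele codes observed at a locus, across all pops."""
        a = self.calls[:, locus, :].ravel()
        return np.unique(a[a != MISSING])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(indices, dtype=int)
        return GenotypeTable(
            ids=[self.ids[i] for i in idx],
            pops=[self.pops[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            coords=None if self.coords is None else self.coords[idx].copy(),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            ids=list(self.ids),
            pops=list(self.pops),
            loci=list(self.loci),
            calls=self.calls.copy(),
            coords=None if self.coords is None else self.coords.copy(),
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.ids == other.ids
            and self.pops == other.pops
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


def _canonical_pairs(calls: np.ndarray) -> np.ndarray:
    """Sort each diploid pair ascending; a half-missing call becomes missing."""
    calls = calls.copy()
    half = (calls == MISSING).any(axis=2) & ~(calls == MISSING).all(axis=2)
    calls[half] = MISSING
    lo = calls.min(axis=2)
    hi = calls.max(axis=2)
    out = np.stack([lo, hi], axis=2)
    miss = (calls == MISSING).all(axis=2)
    out[miss] = MISSING
    return out


# ---------------------------------------------------------------------------
# Genepop I/O


def read_genepop(path, pop_names: Sequence[str] | None = None) -> GenotypeTable:
    """Read a Genepop file (2- or 3-digit allele codes).

    The first line is a title, followed by locus names (one per line, or a
    single comma-separated line), then population blocks separated by lines
    reading ``Pop`` (case-insensitive).  ``00``/``000`` codes mark missing
    alleles and are never interpreted as an allele numbered zero.

    The format carries no population names; blocks are labelled ``pop1``,
    ``pop2``, ... unless ``pop_names`` supplies labels in block order.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty Genepop file")
    # locus names: lines 1.. until the first Pop separator
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _is_pop_sep(lines[i]):
        ln = lines[i].strip()
        if ln:
            loci.extend(x.strip() for x in ln.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: no 'Pop' separator found (line {i})")
    if not loci:
        raise ValueError(f"{path}: no locus names before first 'Pop' (line {i + 1})")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    current_pop = None
    for lineno in range(i, len(lines)):
        ln = lines[lineno].strip()
        if not ln:
            continue
        if _is_pop_sep(ln):
            pop_counter += 1
            if pop_names is not None and pop_counter <= len(pop_names):
                current_pop = str(pop_names[pop_counter - 1])
            else:
                current_pop = f"pop{pop_counter}"
            continue
        if current_pop is None:
            raise ValueError(f"{path}: genotype line before any 'Pop' (line {lineno + 1})")
        if "," not in ln:
            raise ValueError(f"{path}: missing ',' after sample id (line {lineno + 1})")
        name, geno = ln.split(",", 1)
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"{path}: expected {len(loci)} genotypes, got {len(tokens)} "
                f"(line {lineno + 1})"
            )
        row = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"{path}: bad genotype token '{tok}' (line {lineno + 1})")
            w = len(tok) // 2
            a1, a2 = int(tok[:w]), int(tok[w:])
            row.append((a1 if a1 > 0 else MISSING, a2 if a2 > 0 else MISSING))
        ids.append(name)
        pops.append(current_pop)
        rows.append(row)

    calls = np.array(rows, dtype=np.int64) if rows else np.empty((0, len(loci), 2), np.int64)
    return GenotypeTable(ids=ids, pops=pops, loci=loci, calls=calls)


def _is_pop_sep(line: str) -> bool:
    return line.strip().lower() == "pop"


def write_genepop(table: GenotypeTable, path, title: str = "corridorgen export",
                  digits: int = 3) -> None:
    """Write a GenotypeTable as Genepop; missing calls become 000000."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    fmt = f"%0{digits}d"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(loc + "\n")
        for pop in table.pop_names:
            fh.write("Pop\n")
            for i in table.pop_indices(pop):
                toks = []
                for l in range(table.n_loci):
                    a1, a2 = table.calls[i, l]
                    toks.append(
                        (fmt % max(a1, 0)) + (fmt % max(a2, 0))
                    )
                fh.write(f"{table.ids[i]} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Replicate consensus


@dataclass
class ReplicateSet:
    """Replicated genotype calls: per sample and locus, ``n_reps`` diploid calls.

    ``calls`` has shape (n_samples, n_loci, n_reps, 2); -1 marks missing.
    """

    ids: list[str]
    pops: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.ndim != 4 or self.calls.shape[3] != 2:
            raise ValueError("calls must have shape (n, L, n_reps, 2)")
        if self.calls.shape[2] < 2:
            raise ValueError("at least two replicates are required")

    @property
    def n_reps(self) -> int:
        return self.calls.shape[2]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, sid in enumerate(self.ids):
            for l, loc in enumerate(self.loci):
                for r in range(self.n_reps):
                    a1, a2 = self.calls[i, l, r]
                    recs.append((sid, loc, r + 1, int(a1), int(a2)))
        return pd.DataFrame(recs, columns=["sample", "locus", "rep", "a1", "a2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pops: dict[str, str] | None = None
                   ) -> "ReplicateSet":
        ids = list(dict.fromkeys(df["sample"]))
        loci = list(dict.fromkeys(df["locus"]))
        n_reps = int(df["rep"].max())
        calls = np.full((len(ids), len(loci), n_reps, 2), MISSING, np.int64)
        iidx = {s: i for i, s in enumerate(ids)}
        lidx = {l: i for i, l in enumerate(loci)}
        for row in df.itertuples(index=False):
            calls[iidx[row.sample], lidx[row.locus], int(row.rep) - 1] = (row.a1, row.a2)
        poplist = [pops.get(s, "pop1") if pops else "pop1" for s in ids]
        return cls(ids=ids, pops=poplist, loci=loci, calls=calls)


@dataclass
class ConsensusResult:
    """Consensus genotypes with per-sample quality index and retention flag."""

    table: GenotypeTable
    quality_index: np.ndarray          # (n,)
    locus_quality: np.ndarray          # (n, L), NaN where no consensus
    retained: np.ndarray               # (n,) bool
    qi_threshold: float
    min_loci: int

    def retained_table(self) -> GenotypeTable:
        return self.table.subset(np.flatnonzero(self.retained))


def consensus_genotypes(reps: ReplicateSet, qi_threshold: float = 0.75,
                        min_loci: int = 12, min_het_obs: int = 2) -> ConsensusResult:
    """Build consensus genotypes from replicated amplifications.

    Per locus the consensus is the modal diploid call; a heterozygote is only
    accepted if observed in at least ``min_het_obs`` replicates (multiple-tubes
    rule, guarding against false alleles).  Per-locus quality is the fraction
    of non-missing replicates matching the consensus; the sample quality index
    (QI) is its mean over loci with a consensus.  Samples are retained iff
    QI >= ``qi_threshold`` and the number of consensus-typed loci is at least
    ``min_loci``.
    """
    n, L, R, _ = reps.calls.shape
    cons = np.full((n, L, 2), MISSING, np.int64)
    lq = np.full((n, L), np.nan)
    pairs = _canonical_pairs(reps.calls.reshape(n * L * R, 1, 2)).reshape(n, L, R, 2)
    for i in range(n):
        for l in range(L):
            calls = [tuple(c) for c in pairs[i, l] if c[0] != MISSING]
            if not calls:
                continue
            counts: dict[tuple[int, int], int] = {}
            for c in calls:
                counts[c] = counts.get(c, 0) + 1
            # rank by count desc, then lexicographically for determinism
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            chosen = None
            for call, cnt in ranked:
                het = call[0] != call[1]
                if het and cnt < min_het_obs:
                    continue
                chosen = call
                break
            if chosen is None:
                continue
            cons[i, l] = chosen
            lq[i, l] = counts[chosen] / len(calls)
    with np.errstate(invalid="ignore"):
        qi = np.nanmean(lq, axis=1)
    qi = np.where(np.all(np.isnan(lq), axis=1), 0.0, qi)
    typed = (cons != MISSING).all(axis=2).sum(axis=1)
    retained = (qi >= qi_threshold) & (typed >= min_loci)
    table = GenotypeTable(ids=list(reps.ids), pops=list(reps.pops),
                          loci=list(reps.loci), calls=cons)
    return ConsensusResult(table=table, quality_index=qi, locus_quality=lq,
                           retained=retained, qi_threshold=qi_threshold,
                           min_loci=min_loci)


# ---------------------------------------------------------------------------
# Unique-individual identification


def identify_individuals(table: GenotypeTable, min_loci: int = 12,
                         max_mismatch: int = 0
                         ) -> tuple[GenotypeTable, dict[str, list[str]], list[str]]:
    """Collapse repeated captures of the same individual.

    Samples typed at fewer than ``min_loci`` loci are dropped.  Two samples
    are the same individual when they overlap at >= ``min_loci`` typed loci
    and mismatch at <= ``max_mismatch`` of them; matching is closed
    transitively and the representative of each group is the
    lexicographically smallest sample id.

    Returns (unique table, duplicate map {representative: [other ids]},
    dropped ids).
    """
    typed = table.typed_mask()
    keep = np.flatnonzero(typed.sum(axis=1) >= min_loci)
    dropped = [table.ids[i] for i in range(table.n_individuals) if i not in set(keep)]
    sub = table.subset(keep)
    tm = sub.typed_mask()
    n = sub.n_individuals
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n):
        for j in range(i + 1, n):
            both = tm[i] & tm[j]
            if both.sum() < min_loci:
                continue
            mism = (sub.calls[i, both] != sub.calls[j, both]).any(axis=1).sum()
            if mism <= max_mismatch:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps_idx = []
    dup_map: dict[str, list[str]] = {}
    for members in groups.values():
        named = sorted(members, key=lambda i: sub.ids[i])
        rep = named[0]
        reps_idx.append(rep)
        if len(named) > 1:
            dup_map[sub.ids[rep]] = [sub.ids[i] for i in named[1:]]
    reps_idx.sort()
    return sub.subset(reps_idx), dup_map, dropped
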