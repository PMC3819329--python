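"""Diversity, identity probability, HWE, differentiation and relatedness.

Statistics operate on :class:`~corridorgen.genio.GenotypeTable` objects and
an :class:`AlleleFrequencyTable` derived from them.  Differentiation is
measured two ways: Weir–Cockerham theta (variance-components F_ST, the
long-term signal) and the allele-sharing distance D_SP = −ln(mean
proportion of shared alleles between inter-population individual pairs),
which responds to recent gene flow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from corridorgen.genio import MISSING, GenotypeTable


@dataclass
class AlleleFrequencyTable:
    """Per-population, per-locus allele frequencies with gene-copy counts.

    ``alleles[l]`` lists the sorted allele codes observed at locus ``l``
    across *all* populations; ``freqs[l]`` is (n_pops, k_l) and sums to 1
    along axis 1 wherever ``n_copies`` is nonzero.
    """

    pops: list[str]
    loci: list[str]
    alleles: list[np.ndarray]
    freqs: list[np.ndarray]
    n_copies: np.ndarray  # (n_pops, n_loci)

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    def counts(self, locus: int) -> np.ndarray:
        """Allele-copy counts (n_pops, k_l)."""
        return self.freqs[locus] * self.n_copies[:, locus][:, None]

    def pop_index(self, pop: str) -> int:
        return self.pops.index(pop)

    def pooled(self) -> "AlleleFrequencyTable":
        """Collapse populations into one pooled sample (count-weighted)."""
        freqs = []
        ncop = np.zeros((1, len(self.loci)))
        for l in range(len(self.loci)):
            c = self.counts(l).sum(axis=0, keepdims=True)
            tot = c.sum()
            ncop[0, l] = tot
            freqs.append(c / tot if tot > 0 else c)
        return AlleleFrequencyTable(pops=["pooled"], loci=list(self.loci),
                                    alleles=[a.copy() for a in self.alleles],
                                    freqs=freqs, n_copies=ncop)


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencyTable:
    """Observed allele frequencies per population and locus."""
    pops = table.pop_names
    L = table.n_loci
    alleles = [table.alleles_at(l) for l in range(L)]
    n_copies = np.zeros((len(pops), L))
    freqs = []
    for l in range(L):
        k = len(alleles[l])
        f = np.zeros((len(pops), k))
        for pi, pop in enumerate(pops):
            idx = table.pop_indices(pop)
            a = table.calls[idx, l, :].ravel()
            a = a[a != MISSING]
            n_copies[pi, l] = a.size
            if a.size:
                pos = np.searchsorted(alleles[l], a)
                f[pi] = np.bincount(pos, minlength=k) / a.size
        freqs.append(f)
    return AlleleFrequencyTable(pops=pops, loci=list(table.loci),
                                alleles=alleles, freqs=freqs, n_copies=n_copies)


# ---------------------------------------------------------------------------
# Diversity and HWE


def hwe_exact_mc(calls: np.ndarray, n_shuffles: int = 10000,
                 rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo exact Hardy–Weinberg test for one locus.

    ``calls`` is (n, 2) allele codes (missing rows excluded by the caller).
    Gene copies are shuffled and re-paired; the orderliness statistic is the
    conditional log-probability of the genotype configuration given the
    allele counts (up to terms constant under shuffling:
    h·ln2 − Σ_g ln(n_g!)).  p = fraction of shuffled configurations no more
    probable than the observed one, with the +1 correction so p > 0.
    """
    rng = np.random.default_rng() if rng is None else rng
    calls = np.asarray(calls)
    calls = calls[(calls != MISSING).all(axis=1)]
    n = len(calls)
    if n == 0:
        return 1.0
    copies = calls.ravel()
    if np.unique(copies).size < 2:
        return 1.0

    def stat(pairs: np.ndarray) -> np.ndarray:
        # pairs: (m, n, 2) sorted within pair
        a, b = pairs[..., 0], pairs[..., 1]
        h = (a != b).sum(axis=1)
        # sum over genotypes of ln(count!) via run lengths of sorted codes
        code = a * (copies.max() + 1) + b
        s = np.sort(code, axis=1)
        new = np.ones_like(s, dtype=bool)
        new[:, 1:] = s[:, 1:] != s[:, :-1]
        pos = np.broadcast_to(np.arange(n), s.shape)
        start = np.where(new, pos, 0)
        start = np.maximum.accumulate(start, axis=1)
        runpos = pos - start + 1
        return h * np.log(2.0) - np.log(runpos).sum(axis=1)

    obs_pairs = np.sort(calls, axis=1)[None, :, :]
    s_obs = stat(obs_pairs)[0]
    mat = np.broadcast_to(copies, (n_shuffles, 2 * n)).copy()
    mat = rng.permuted(mat, axis=1)
    perm_pairs = np.sort(mat.reshape(n_shuffles, n, 2), axis=2)
    s_perm = stat(perm_pairs)
    return (1 + int((s_perm <= s_obs + 1e-9).sum())) / (n_shuffles + 1)


def diversity(table: GenotypeTable, n_shuffles: int = 10000,
              seed: int | None = None) -> pd.DataFrame:
    """Per-locus diversity summary over the whole table.

    Columns: ``Al`` (alleles), ``He`` (unbiased expected heterozygosity,
    2n/(2n−1) correction), ``Ho`` (observed), ``hwe_p`` (Monte-Carlo exact
    test).  Monomorphic loci get He = 0 and hwe_p = 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for l, loc in enumerate(table.loci):
        calls = table.calls[:, l, :]
        typed = calls[(calls != MISSING).all(axis=1)]
        n = len(typed)
        if n == 0:
            rows.append((loc, 0, np.nan, np.nan, np.nan))
            continue
        copies = typed.ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / copies.size
        al = len(counts)
        he = (1 - (p ** 2).sum())
        if copies.size > 1:
            he *= copies.size / (copies.size - 1)
        ho = float((typed[:, 0] != typed[:, 1]).mean())
        pval = 1.0 if al < 2 else hwe_exact_mc(typed, n_shuffles=n_shuffles, rng=rng)
        rows.append((loc, al, he, ho, pval))
    return pd.DataFrame(rows, columns=["locus", "Al", "He", "Ho", "hwe_p"]
                        ).set_index("locus")


def pid_sibs(freqs: AlleleFrequencyTable, pop: str | None = None,
             loci: list[str] | None = None) -> float:
    """Probability of identity among siblings across the given loci.

    Per locus: 0.25 + 0.5·Σp² + 0.5·(Σp²)² − 0.25·Σp⁴; multiplied across
    loci.  With ``pop=None`` frequencies are pooled over populations.
    """
    ft = freqs.pooled() if pop is None else freqs
    pi = 0 if pop is None else ft.pop_index(pop)
    if loci is None:
        loci = list(ft.loci)
    if not loci:
        raise ValueError("empty locus list")
    out = 1.0
    for loc in loci:
        l = ft.loci.index(loc)
        p = ft.freqs[l][pi]
        s2 = float((p ** 2).sum())
        s4 = float((p ** 4).sum())
        out *= 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _wc_components(table: GenotypeTable, pops: list[str]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components (a, b, c), each summed
    over alleles.  Loci with no data in a population contribute NaN."""
    r = len(pops)
    L = table.n_loci
    A = np.full(L, np.nan)
    B = np.full(L, np.nan)
    C = np.full(L, np.nan)
    idx = [table.pop_indices(p) for p in pops]
    for l in range(L):
        alleles = table.alleles_at(l)
        if alleles.size == 0:
            continue
        ni = np.zeros(r)
        pmat = np.zeros((r, alleles.size))
        hmat = np.zeros((r, alleles.size))
        ok = True
        for i in range(r):
            calls = table.calls[idx[i], l, :]
            typed = calls[(calls != MISSING).all(axis=1)]
            ni[i] = len(typed)
            if len(typed) == 0:
                ok = False
                break
            pos = np.searchsorted(alleles, typed)
            for a in range(alleles.size):
                cnt = (pos == a).sum(axis=1)
                pmat[i, a] = cnt.sum() / (2 * len(typed))
                hmat[i, a] = (cnt == 1).mean()
        if not ok or ni.sum() == 0:
            continue
        nbar = ni.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ni ** 2).sum() / (r * nbar)) / (r - 1)
        asum = bsum = csum = 0.0
        for a in range(alleles.size):
            pbar = (ni * pmat[:, a]).sum() / (r * nbar)
            s2 = (ni * (pmat[:, a] - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ni * hmat[:, a]).sum() / (r * nbar)
            av = (nbar / nc) * (s2 - (1.0 / (nbar - 1)) *
                                (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
            bv = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                        - (2 * nbar - 1) / (4 * nbar) * hbar)
            cv = hbar / 2
            asum += av
            bsum += bv
            csum += cv
        A[l], B[l], C[l] = asum, bsum, csum
    return A, B, C


@dataclass
class FstResult:
    theta: float
    se: float
    p_value: float | None
    per_locus: pd.DataFrame


def fst_wc(table: GenotypeTable, popA: str, popB: str, n_perm: int = 0,
           seed: int | None = None) -> FstResult:
    """Pairwise Weir–Cockerham theta with leave-one-locus-out jackknife SE.

    The multilocus estimate is the ratio of summed variance components
    Σa / Σ(a+b+c).  With ``n_perm`` > 0 a permutation p-value is computed
    by shuffling individuals between the two populations.
    """
    a, b, c = _wc_components(table, [popA, popB])
    theta = _theta_from_components(a, b, c)
    if np.isnan(theta):
        raise ValueError(f"theta undefined for ({popA},{popB}): no variation")
    ok = np.flatnonzero(~np.isnan(a))
    loo = []
    for l in ok:
        m = ok[ok != l]
        loo.append(_theta_from_components(a[m], b[m], c[m]))
    loo = np.asarray(loo, dtype=float)
    nl = len(loo)
    se = float(np.sqrt((nl - 1) / nl * ((loo - loo.mean()) ** 2).sum())) if nl > 1 else np.nan
    pval = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        idx = np.concatenate([table.pop_indices(popA), table.pop_indices(popB)])
        nA = len(table.pop_indices(popA))
        sub = table.subset(idx)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(sub.n_individuals)
            shuf = sub.copy()
            shuf.pops = ["A" if i in set(perm[:nA]) else "B"
                         for i in range(sub.n_individuals)]
            ap, bp, cp = _wc_components(shuf, ["A", "B"])
            tp = _theta_from_components(ap, bp, cp)
            if not np.isnan(tp) and tp >= theta - 1e-12:
                count += 1
        pval = (count + 1) / (n_perm + 1)
    per_locus = pd.DataFrame({"a": a, "b": b, "c": c}, index=table.loci)
    return FstResult(theta=float(theta), se=se, p_value=pval, per_locus=per_locus)


def _theta_from_components(a, b, c) -> float:
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    m = ~np.isnan(a)
    denom = (a[m] + b[m] + c[m]).sum()
    if denom == 0 or m.sum() == 0:
        return np.nan
    return float(a[m].sum() / denom)


# ---------------------------------------------------------------------------
# Allele-sharing distance D_SP


def _sharing_matrix(table: GenotypeTable, idxA: np.ndarray, idxB: np.ndarray
                    ) -> np.ndarray:
    """Per inter-population pair and locus, proportion of shared alleles.

    shared(g1, g2) = Σ_alleles min(count_g1, count_g2) / 2; NaN where either
    genotype is missing.  Shape (len(idxA)*len(idxB), L).
    """
    L = table.n_loci
    out = np.full((len(idxA) * len(idxB), L), np.nan)
    for l in range(L):
        cA = table.calls[idxA, l, :]
        cB = table.calls[idxB, l, :]
        okA = (cA != MISSING).all(axis=1)
        okB = (cB != MISSING).all(axis=1)
        # pairwise shared-allele count via sorted-pair comparison
        a1 = cA[:, 0][:, None]
        a2 = cA[:, 1][:, None]
        b1 = cB[:, 0][None, :]
        b2 = cB[:, 1][None, :]
        # count of matching allele copies between two unordered pairs
        s11 = (a1 == b1)
        s12 = (a1 == b2)
        s21 = (a2 == b1)
        s22 = (a2 == b2)
        # maximum matching on a 2x2 bipartite graph
        two = (s11 & s22) | (s12 & s21)
        one = s11 | s12 | s21 | s22
        shared = np.where(two, 2, np.where(one, 1, 0)).astype(float)
        shared[~okA, :] = np.nan
        shared[:, ~okB] = np.nan
        out[:, l] = (shared / 2.0).ravel()
    return out


def dsp(table: GenotypeTable, popA: str, popB: str, variant: str = "log"
        ) -> tuple[float, float]:
    """Allele-sharing distance between two populations with jackknife SE.

    ps = mean over loci, then over inter-population individual pairs, of the
    proportion of shared alleles.  ``variant='log'`` returns −ln(ps) (the
    default, unbounded above); ``variant='one_minus'`` returns 1 − ps.
    """
    if variant not in ("log", "one_minus"):
        raise ValueError("variant must be 'log' or 'one_minus'")
    idxA = table.pop_indices(popA)
    idxB = table.pop_indices(popB)
    S = _sharing_matrix(table, idxA, idxB)

    def value(cols: np.ndarray) -> float:
        if len(cols) == 0:
            return np.nan
        sub = S[:, cols]
        counts = (~np.isnan(sub)).sum(axis=1)
        per_pair = np.nansum(sub, axis=1)[counts > 0] / counts[counts > 0]
        if per_pair.size == 0:
            return np.nan
        ps = float(per_pair.mean())
        if variant == "log":
            return float(np.inf) if ps <= 0 else -float(np.log(ps))
        return 1.0 - ps

    L = table.n_loci
    full = value(np.arange(L))
    loo = np.array([value(np.delete(np.arange(L), l)) for l in range(L)])
    loo = loo[np.isfinite(loo)]
    nl = len(loo)
    se = float(np.sqrt((nl - 1) / nl * ((loo - loo.mean()) ** 2).sum())) if nl > 1 else np.nan
    return full, se


# ---------------------------------------------------------------------------
# Pairwise matrices


@dataclass
class PairwiseMatrix:
    """Square population-by-population matrix with optional SEs."""

    labels: list[str]
    values: np.ndarray
    se: np.ndarray | None = None
    symmetric: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def se_frame(self) -> pd.DataFrame | None:
        if self.se is None:
            return None
        return pd.DataFrame(self.se, index=self.labels, columns=self.labels)


def pairwise_fst(table: GenotypeTable, n_perm: int = 0, seed: int | None = None
                 ) -> PairwiseMatrix:
    pops = table.pop_names
    n = len(pops)
    V = np.zeros((n, n))
    E = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        res = fst_wc(table, pops[i], pops[j], n_perm=n_perm, seed=seed)
        V[i, j] = V[j, i] = res.theta
        E[i, j] = E[j, i] = res.se
    return PairwiseMatrix(labels=pops, values=V, se=E, symmetric=True)


def pairwise_dsp(table: GenotypeTable, variant: str = "log") -> PairwiseMatrix:
    pops = table.pop_names
    n = len(pops)
    V = np.zeros((n, n))
    E = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        v, se = dsp(table, pops[i], pops[j], variant=variant)
        V[i, j] = V[j, i] = v
        E[i, j] = E[j, i] = se
    return PairwiseMatrix(labels=pops, values=V, se=E, symmetric=True)


# ---------------------------------------------------------------------------
# Maximum-likelihood relatedness


RELATIONSHIP_POINTS = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


@dataclass
class RelatednessEstimate:
    pair: tuple[str, str]
    k: tuple[float, float, float]
    r: float
    category: str
    loglik: float
    category_logliks: dict[str, float]


def _pair_ibd_probs(g1: np.ndarray, g2: np.ndarray, p: np.ndarray,
                    alleles: np.ndarray) -> tuple[float, float, float]:
    """P(G1,G2 | IBD state) at one locus for 0/1/2 alleles shared IBD."""
    def freq(code):
        return float(p[np.searchsorted(alleles, code)])

    a, b = int(g1[0]), int(g1[1])
    c, d = int(g2[0]), int(g2[1])
    pa, pb = freq(a), freq(b)

    def pg(x, y):
        return freq(x) ** 2 if x == y else 2 * freq(x) * freq(y)

    P1g1 = pg(a, b)
    P0 = P1g1 * pg(c, d)
    # conditional P(G2 | G1, one allele IBD)
    if a == b:
        if c == d:
            cond = freq(a) if c == a else 0.0
        else:
            cond = freq(d) if c == a else (freq(c) if d == a else 0.0)
    else:
        if c == d:
            cond = freq(a) / 2 if c == a else (freq(b) / 2 if c == b else 0.0)
        else:
            cond = 0.0
            if {c, d} == {a, b}:
                cond = (pa + pb) / 2
            elif c == a or c == b:
                cond = freq(d) / 2
            elif d == a or d == b:
                cond = freq(c) / 2
    P1 = P1g1 * cond
    P2 = P1g1 * (1.0 if (a, b) == (c, d) else 0.0)
    return P0, P1, P2


def ml_relatedness(table: GenotypeTable, pair: tuple[str, str],
                   freqs: AlleleFrequencyTable | None = None,
                   frequencies: str = "pooled") -> RelatednessEstimate:
    """ML estimate of the IBD coefficients (k0, k1, k2) for a pair.

    The likelihood mixes the 0/1/2-IBD genotype-pair probabilities and is
    maximised over the simplex by a coarse grid plus constrained local
    refinement; r = k2 + k1/2.  ``frequencies`` selects pooled allele
    frequencies (default, as when all individuals are entered as one
    population) or the first individual's own population.
    """
    i = table.ids.index(pair[0])
    j = table.ids.index(pair[1])
    if freqs is None:
        freqs = allele_frequencies(table)
    if frequencies == "pooled":
        ft = freqs.pooled()
        pi = 0
    elif frequencies == "population":
        ft = freqs
        pi = ft.pop_index(table.pops[i])
    else:
        raise ValueError("frequencies must be 'pooled' or 'population'")

    probs = []
    for l in range(table.n_loci):
        g1 = table.calls[i, l]
        g2 = table.calls[j, l]
        if MISSING in g1 or MISSING in g2:
            continue
        probs.append(_pair_ibd_probs(g1, g2, ft.freqs[l][pi], ft.alleles[l]))
    if not probs:
        raise ValueError(f"pair {pair} shares no typed loci")
    P = np.asarray(probs)  # (L, 3)

    def negll(k12: np.ndarray) -> float:
        k1, k2 = k12
        k0 = 1.0 - k1 - k2
        mix = P @ np.array([k0, k1, k2])
        if (mix <= 0).any():
            return 1e12
        return -float(np.log(mix).sum())

    # coarse grid on the simplex
    best = (0.0, 0.0)
    best_v = negll(np.array(best))
    step = 0.02
    for k1 in np.arange(0, 1 + 1e-9, step):
        for k2 in np.arange(0, 1 - k1 + 1e-9, step):
            v = negll(np.array([k1, k2]))
            if v < best_v - 1e-12:
                best_v, best = v, (float(k1), float(k2))
    res = optimize.minimize(
        negll, x0=np.array(best), method="SLSQP",
        bounds=[(0, 1), (0, 1)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}],
        options={"ftol": 1e-10, "maxiter": 200},
    )
    k1, k2 = (res.x if res.fun <= best_v else np.array(best))
    k1 = float(np.clip(k1, 0, 1))
    k2 = float(np.clip(k2, 0, 1 - k1))
    k0 = 1.0 - k1 - k2
    ll = -negll(np.array([k1, k2]))

    cat_ll = {}
    for name, (c0, c1, c2) in RELATIONSHIP_POINTS.items():
        mix = P @ np.array([c0, c1, c2])
        cat_ll[name] = -np.inf if (mix <= 0).any() else float(np.log(mix).sum())
    category = max(cat_ll, key=lambda nm: cat_ll[nm])
    return RelatednessEstimate(pair=pair, k=(k0, k1, k2), r=k2 + k1 / 2,
                               category=category, loglik=ll,
                               category_logliks=cat_ll)
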