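"""Bayesian assignment, first-generation-migrant detection and migration rates.

The assignment criterion is the posterior-predictive genotype likelihood of
Rannala & Mountain: with a Dirichlet(1/k) prior on a population's allele
frequencies (k = alleles seen at the locus across all populations), the two
allele copies of a genotype are drawn sequentially, so an allele never seen
in a reference population still has finite probability.  Migrant detection
uses the log-likelihood ratio Λ = log10(L_max / L_home) with a Monte-Carlo
null built from genotypes resampled from the home population's observed
frequencies; large Λ and a small upper-tail p mean the individual is an
unlikely resident.  A complementary population-prior model scores each
individual as resident / F0 migrant / one-migrant-parent (F1) under a
migration prior ν.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from corridorgen.genio import MISSING, GenotypeTable
from corridorgen.popgen import AlleleFrequencyTable, allele_frequencies


def _locus_arrays(freqs: AlleleFrequencyTable):
    """Per-locus allele counts (n_pops, k) and k = number of alleles."""
    counts = [freqs.counts(l) for l in range(len(freqs.loci))]
    ks = [c.shape[1] for c in counts]
    return counts, ks


def rm_log10_likelihood(calls: np.ndarray, freqs: AlleleFrequencyTable,
                        pop: str) -> float:
    """Rannala–Mountain log10 genotype likelihood for one individual.

    ``calls`` is (L, 2) allele codes; loci missing in the individual, or
    with zero gene copies in the reference population, are skipped.
    Per locus the probability of drawing the two alleles sequentially from
    the Dirichlet posterior is
    (n_a + 1/k)/(n + 1) · (n_b + 1/k + δ_ab)/(n + 2), doubled for
    heterozygotes.
    """
    pi = freqs.pop_index(pop)
    total = 0.0
    for l in range(len(freqs.loci)):
        a, b = calls[l]
        if a == MISSING:
            continue
        cnt = freqs.counts(l)[pi]
        n = cnt.sum()
        if n <= 0:
            continue
        k = len(freqs.alleles[l])
        ia = int(np.searchsorted(freqs.alleles[l], a))
        ib = int(np.searchsorted(freqs.alleles[l], b))
        if ia >= k or freqs.alleles[l][ia] != a or ib >= k or freqs.alleles[l][ib] != b:
            raise ValueError(f"allele not in locus {freqs.loci[l]} allele set")
        p1 = (cnt[ia] + 1.0 / k) / (n + 1.0)
        p2 = (cnt[ib] + 1.0 / k + (1.0 if ia == ib else 0.0)) / (n + 2.0)
        prob = p1 * p2 * (1.0 if ia == ib else 2.0)
        total += np.log10(prob)
    return float(total)


def _rm_scores_bulk(idx_calls: list[np.ndarray], counts: list[np.ndarray],
                    ks: list[int]) -> np.ndarray:
    """log10 likelihood of many genotypes in every population, vectorized.

    ``idx_calls[l]`` is (n_geno, 2) allele *indices* at locus l, or -1 for
    missing.  Returns (n_geno, n_pops).
    """
    n_geno = idx_calls[0].shape[0]
    n_pops = counts[0].shape[0]
    out = np.zeros((n_geno, n_pops))
    for l, (idx, cnt) in enumerate(zip(idx_calls, counts)):
        k = ks[l]
        n = cnt.sum(axis=1)  # (n_pops,)
        ok = idx[:, 0] >= 0
        ia = np.where(ok, idx[:, 0], 0)
        ib = np.where(ok, idx[:, 1], 0)
        ca = cnt[:, ia].T  # (n_geno, n_pops)
        cb = cnt[:, ib].T
        hom = (ia == ib)
        p1 = (ca + 1.0 / k) / (n + 1.0)
        p2 = (cb + 1.0 / k + hom[:, None]) / (n + 2.0)
        lg = np.log10(p1 * p2 * np.where(hom, 1.0, 2.0)[:, None])
        lg[~ok] = 0.0
        lg[:, n <= 0] = 0.0
        out += lg
    return out


def _calls_to_indices(table: GenotypeTable, freqs: AlleleFrequencyTable
                      ) -> list[np.ndarray]:
    idx_calls = []
    for l in range(len(freqs.loci)):
        codes = table.calls[:, l, :]
        pos = np.searchsorted(freqs.alleles[l], codes)
        pos[codes == MISSING] = -1
        idx_calls.append(pos)
    return idx_calls


def assignment_scores(table: GenotypeTable,
                      freqs: AlleleFrequencyTable | None = None,
                      leave_one_out: bool = True) -> pd.DataFrame:
    """log10 assignment likelihood of every individual in every population.

    With ``leave_one_out`` an individual's own alleles are removed from its
    home population's counts before scoring it there, so its genotype never
    inflates its own reference frequencies.
    """
    freqs = freqs or allele_frequencies(table)
    counts, ks = _locus_arrays(freqs)
    idx_calls = _calls_to_indices(table, freqs)
    scores = _rm_scores_bulk(idx_calls, counts, ks)
    if leave_one_out:
        pop_of = [freqs.pop_index(p) for p in table.pops]
        for i in range(table.n_individuals):
            pi = pop_of[i]
            total = 0.0
            for l in range(len(freqs.loci)):
                ia, ib = idx_calls[l][i]
                if ia < 0:
                    continue
                cnt = counts[l][pi].copy()
                cnt[ia] -= 1
                cnt[ib] -= 1
                if (cnt < -1e-9).any():
                    raise ValueError("leave-one-out counts went negative; "
                                     "frequencies do not match the table")
                n = cnt.sum()
                if n <= 0:
                    continue
                k = ks[l]
                hom = ia == ib
                p1 = (cnt[ia] + 1.0 / k) / (n + 1.0)
                p2 = (cnt[ib] + 1.0 / k + (1.0 if hom else 0.0)) / (n + 2.0)
                total += np.log10(p1 * p2 * (1.0 if hom else 2.0))
            scores[i, pi] = total
    return pd.DataFrame(scores, index=table.ids, columns=freqs.pops)


def _simulate_null_lambda(freqs: AlleleFrequencyTable, home: str, n_sim: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Null Λ distribution for residents of ``home``.

    Multilocus genotypes are built by drawing allele copies with replacement
    from the home population's observed frequencies (Monte-Carlo resampling,
    not a parametric Dirichlet draw), then scored in every population.
    """
    counts, ks = _locus_arrays(freqs)
    pi = freqs.pop_index(home)
    idx_calls = []
    for l in range(len(freqs.loci)):
        cnt = counts[l][pi]
        n = cnt.sum()
        if n <= 0:
            idx_calls.append(np.full((n_sim, 2), -1, dtype=np.int64))
            continue
        p = cnt / n
        draws = rng.choice(len(p), size=(n_sim, 2), p=p)
        idx_calls.append(np.sort(draws, axis=1))
    scores = _rm_scores_bulk(idx_calls, counts, ks)
    lam = scores.max(axis=1) - scores[:, pi]
    return lam


@dataclass
class MigrantCall:
    id: str
    sampled: str
    assigned: str
    lambda_: float
    p_resident: float
    flagged: bool


def detect_migrants(table: GenotypeTable, alpha: float = 0.01,
                    n_sim: int = 10000, seed: int | None = None,
                    freqs: AlleleFrequencyTable | None = None) -> pd.DataFrame:
    """First-generation migrant detection with a resampling null.

    Λ = log10(L_max/L_home) is computed with leave-one-out home frequencies;
    the null distribution per home population comes from ``n_sim`` simulated
    resident genotypes; p_resident is the upper-tail fraction of null Λ at
    or above the observed value (ties counted, +1 correction), and an
    individual is flagged iff p_resident < ``alpha``.

    Returns a Table-2-style frame: id, sampled, assigned, lambda, p_resident,
    flagged.
    """
    if len(table.pop_names) < 2:
        raise ValueError("migrant detection needs >= 2 populations")
    rng = np.random.default_rng(seed)
    freqs = freqs or allele_frequencies(table)
    scores = assignment_scores(table, freqs=freqs, leave_one_out=True)
    null: dict[str, np.ndarray] = {}
    for pop in freqs.pops:
        n_in_pop = len(table.pop_indices(pop))
        if 0 < n_in_pop < 3:
            import warnings
            warnings.warn(f"population {pop} has {n_in_pop} individuals; "
                          "the resampling null is poorly calibrated")
        null[pop] = np.sort(_simulate_null_lambda(freqs, pop, n_sim, rng))
    rows = []
    S = scores.to_numpy()
    pops = list(scores.columns)
    for i, sid in enumerate(table.ids):
        home = table.pops[i]
        hi = pops.index(home)
        best = int(np.argmax(S[i]))
        lam = float(S[i, best] - S[i, hi])
        nd = null[home]
        # upper tail with ties counted as >=
        p = (1 + len(nd) - int(np.searchsorted(nd, lam - 1e-12, side="left"))) \
            / (len(nd) + 1)
        rows.append(MigrantCall(id=sid, sampled=home, assigned=pops[best],
                                lambda_=lam, p_resident=p,
                                flagged=bool(p < alpha)))
    return pd.DataFrame([r.__dict__ for r in rows]).rename(
        columns={"lambda_": "lambda"})


# ---------------------------------------------------------------------------
# Population-prior migrant posterior (resident / F0 / F1)


def migrant_posterior(table: GenotypeTable, nu: float = 0.05,
                      gensback: int = 1,
                      freqs: AlleleFrequencyTable | None = None,
                      leave_one_out: bool = True) -> pd.DataFrame:
    """Posterior over resident / F0-migrant / F1 (one migrant parent).

    Priors: resident 1 − ν; F0 from each other population ν/2 divided
    equally; F1 likewise ν/2.  The F0 likelihood scores the genotype on the
    source population; the F1 likelihood averages over the phase of which
    allele came from the migrant parent.  Reported per individual:
    p_resident, the per-source F0 and F1 probabilities, and
    migrant_probability = 1 − p_resident.
    """
    if not (0 <= nu < 1):
        raise ValueError("nu must lie in [0, 1)")
    if gensback != 1:
        raise ValueError("only gensback=1 (resident/F0/F1) is supported")
    freqs = freqs or allele_frequencies(table)
    pops = freqs.pops
    counts, ks = _locus_arrays(freqs)
    idx_calls = _calls_to_indices(table, freqs)
    rows = []
    for i, sid in enumerate(table.ids):
        home = table.pops[i]
        hi = freqs.pop_index(home)
        others = [p for p in pops if p != home]
        # smoothed allele-draw probabilities, leave-one-out at home
        ptilde = []
        for l in range(len(freqs.loci)):
            cnt = counts[l].copy()
            ia, ib = idx_calls[l][i]
            if leave_one_out and ia >= 0:
                cnt[hi, ia] -= 1
                cnt[hi, ib] -= 1
                cnt[hi] = np.maximum(cnt[hi], 0.0)
            n = cnt.sum(axis=1, keepdims=True)
            k = ks[l]
            ptilde.append((cnt + 1.0 / k) / np.maximum(n + 1.0, 1.0))
        loglik = {"resident": _pair_loglik(idx_calls, ptilde, i, hi, hi)}
        for src in others:
            si = freqs.pop_index(src)
            loglik[f"F0:{src}"] = _pair_loglik(idx_calls, ptilde, i, si, si)
            loglik[f"F1:{src}"] = _pair_loglik(idx_calls, ptilde, i, hi, si)
        prior = {"resident": 1.0 - nu}
        for src in others:
            prior[f"F0:{src}"] = nu / 2 / len(others)
            prior[f"F1:{src}"] = nu / 2 / len(others)
        keys = list(loglik)
        logpost = np.array([np.log(max(prior[k], 0.0)) + loglik[k]
                            if prior[k] > 0 else -np.inf for k in keys])
        logpost -= logpost.max()
        post = np.exp(logpost)
        post /= post.sum()
        rec = {"id": sid, "sampled": home, "nu": nu,
               "p_resident": float(post[keys.index("resident")])}
        rec["migrant_probability"] = 1.0 - rec["p_resident"]
        for k, v in zip(keys, post):
            if k != "resident":
                rec[k] = float(v)
        rows.append(rec)
    return pd.DataFrame(rows)


def _pair_loglik(idx_calls, ptilde, i: int, pi1: int, pi2: int) -> float:
    """ln likelihood of individual i's genotype with one allele drawn from
    population pi1 and the other from pi2 (phase summed)."""
    total = 0.0
    for l, idx in enumerate(idx_calls):
        ia, ib = idx[i]
        if ia < 0:
            continue
        p1 = ptilde[l][pi1]
        p2 = ptilde[l][pi2]
        if ia == ib:
            prob = p1[ia] * p2[ia]
        else:
            prob = p1[ia] * p2[ib] + p1[ib] * p2[ia]
        total += np.log(max(prob, 1e-300))
    return total


# ---------------------------------------------------------------------------
# Assignment-derived migration rates


@dataclass
class MigrationRates:
    """Row-stochastic matrix m_ij = share of pop-i samples attributed to j."""

    labels: list[str]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)

    def emigration(self) -> pd.Series:
        off = self.matrix.copy()
        np.fill_diagonal(off, 0.0)
        return pd.Series(off.sum(axis=1), index=self.labels, name="emigration")

    def immigration(self) -> pd.Series:
        off = self.matrix.copy()
        np.fill_diagonal(off, 0.0)
        col = off.sum(axis=0)
        tot = np.maximum(self.matrix.sum(axis=0), 1e-300)
        return pd.Series(col / tot, index=self.labels, name="immigration")


def migration_matrices(calls: pd.DataFrame, pops: list[str] | None = None
                       ) -> MigrationRates:
    """Migration-rate matrix from migrant calls or posteriors.

    Accepts either the ``detect_migrants`` output (hard assignment: a
    flagged individual counts toward its assigned population, others toward
    home) or the ``migrant_posterior`` output (posterior mass spread over
    resident/F0 hypotheses; F1 mass stays at home).
    """
    if "assigned" in calls.columns:
        labels = pops or sorted(set(calls["sampled"]) | set(calls["assigned"]))
        k = len(labels)
        m = np.zeros((k, k))
        for row in calls.itertuples(index=False):
            i = labels.index(row.sampled)
            j = labels.index(row.assigned if row.flagged else row.sampled)
            m[i, j] += 1.0
    elif "p_resident" in calls.columns:
        labels = pops or sorted(set(calls["sampled"]))
        k = len(labels)
        m = np.zeros((k, k))
        f0cols = [c for c in calls.columns if c.startswith("F0:")]
        for row in calls.itertuples(index=False):
            d = row._asdict()
            i = labels.index(d["sampled"])
            stay = 1.0
            for c in f0cols:
                j = labels.index(c.split(":", 1)[1])
                mass = float(d.get(c, 0.0) or 0.0)
                m[i, j] += mass
                stay -= mass
            m[i, i] += stay
    else:
        raise ValueError("unrecognized calls frame")
    rows = m.sum(axis=1)
    if (rows == 0).any():
        empty = [labels[i] for i in np.flatnonzero(rows == 0)]
        raise ValueError(f"no individuals for population(s) {empty}")
    return MigrationRates(labels=labels, matrix=m / rows[:, None])
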