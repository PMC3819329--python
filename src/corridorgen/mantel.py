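"""Simple and partial Mantel tests with permutation significance.

Matrices are vectorized to their upper off-diagonal entries when symmetric,
or to all n(n−1) off-diagonal entries when asymmetric (immigration and
emigration rate matrices); significance comes from jointly permuting the
row and column labels of the second matrix.  For n ≤ 7 labels all n!
permutations are enumerated and the p-value is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

EXHAUSTIVE_MAX_N = 7


@dataclass
class MantelResult:
    r: float
    r2: float
    p: float
    n_perm: int
    exhaustive: bool
    partial: bool
    seed: int | None = None
    labels: tuple[str, str] | tuple[str, str, str] | None = None

    def __repr__(self) -> str:  # compact, Tables-3-6 style
        kind = "partial Mantel" if self.partial else "Mantel"
        return (f"<{kind} r={self.r:.4f} r2={self.r2:.4f} p={self.p:.4g} "
                f"({'exact' if self.exhaustive else f'{self.n_perm} perms'})>")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("Mantel inputs must be square matrices")
    return X


def _offdiag_vector(X: np.ndarray, symmetric: bool) -> np.ndarray:
    n = X.shape[0]
    if symmetric:
        iu = np.triu_indices(n, k=1)
        return X[iu]
    mask = ~np.eye(n, dtype=bool)
    return X[mask]


def _is_symmetric(X: np.ndarray) -> bool:
    return np.allclose(X, X.T, equal_nan=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    d = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
    if d == 0:
        raise ValueError("constant matrix: correlation undefined")
    return float((xs * ys).sum() / d)


def _permutations(n: int, n_perm: int, rng: np.random.Generator
                  ) -> tuple[np.ndarray, bool]:
    if n <= EXHAUSTIVE_MAX_N:
        return np.array(list(itertools.permutations(range(n)))), True
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    return perms, False


def mantel(X, Y, n_perm: int = 9999, seed: int | None = None,
           tail: str = "two") -> MantelResult:
    """Mantel test between two co-labelled square matrices.

    r is the Pearson correlation of the vectorized off-diagonal entries
    (upper triangle when both matrices are symmetric, all off-diagonal
    entries otherwise); p permutes Y's row and column labels jointly, with
    the +1 correction — exact enumeration when n ≤ 7.
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if X.shape != Y.shape:
        raise ValueError("matrices must share shape and label order")
    sym = _is_symmetric(X) and _is_symmetric(Y)
    x = _offdiag_vector(X, sym)
    r_obs = _pearson(x, _offdiag_vector(Y, sym))
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutations(X.shape[0], n_perm, rng)
    stats = np.empty(len(perms))
    for idx, perm in enumerate(perms):
        stats[idx] = _pearson(x, _offdiag_vector(Y[np.ix_(perm, perm)], sym))
    p = _perm_pvalue(r_obs, stats, tail, exhaustive)
    return MantelResult(r=r_obs, r2=r_obs ** 2, p=p,
                        n_perm=len(perms), exhaustive=exhaustive,
                        partial=False, seed=seed)


def _perm_pvalue(r_obs: float, stats: np.ndarray, tail: str,
                 exhaustive: bool) -> float:
    if tail == "two":
        hits = int((np.abs(stats) >= abs(r_obs) - 1e-12).sum())
    elif tail == "greater":
        hits = int((stats >= r_obs - 1e-12).sum())
    elif tail == "less":
        hits = int((stats <= r_obs + 1e-12).sum())
    else:
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    if exhaustive:
        return hits / len(stats)  # identity permutation included, so p > 0
    return (hits + 1) / (len(stats) + 1)


def partial_mantel(X, Y, Z, n_perm: int = 9999, seed: int | None = None,
                   tail: str = "two") -> MantelResult:
    """Partial Mantel test of X vs Y conditioning on Z.

    Both X and Y are residualized entrywise on Z by linear regression; the
    residualized Y is folded back into matrix form and its labels permuted
    (Smouse–Long–Sokal convention).
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    Z = _as_matrix(Z)
    if not (X.shape == Y.shape == Z.shape):
        raise ValueError("matrices must share shape and label order")
    sym = _is_symmetric(X) and _is_symmetric(Y) and _is_symmetric(Z)
    xv = _offdiag_vector(X, sym)
    yv = _offdiag_vector(Y, sym)
    zv = _offdiag_vector(Z, sym)
    if np.allclose(zv, zv[0]):
        import warnings
        warnings.warn("conditioning matrix is constant; "
                      "partial Mantel reduces to a simple Mantel test")
        res = mantel(X, Y, n_perm=n_perm, seed=seed, tail=tail)
        return MantelResult(r=res.r, r2=res.r2, p=res.p, n_perm=res.n_perm,
                            exhaustive=res.exhaustive, partial=True, seed=seed)

    def residuals(v: np.ndarray) -> np.ndarray:
        A = np.stack([np.ones_like(zv), zv], axis=1)
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    rx = residuals(xv)
    ry = residuals(yv)
    r_obs = _pearson(rx, ry)
    # fold residualized Y back into a matrix so labels can be permuted
    n = X.shape[0]
    RY = np.zeros((n, n))
    if sym:
        iu = np.triu_indices(n, k=1)
        RY[iu] = ry
        RY = RY + RY.T
    else:
        RY[~np.eye(n, dtype=bool)] = ry
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutations(n, n_perm, rng)
    stats = np.empty(len(perms))
    for idx, perm in enumerate(perms):
        stats[idx] = _pearson(rx, _offdiag_vector(RY[np.ix_(perm, perm)], sym))
    p = _perm_pvalue(r_obs, stats, tail, exhaustive)
    return MantelResult(r=r_obs, r2=r_obs ** 2, p=p, n_perm=len(perms),
                        exhaustive=exhaustive, partial=True, seed=seed)


def ibd_test(genetic, coords, n_perm: int = 9999, seed: int | None = None
             ) -> MantelResult:
    """Isolation-by-distance Mantel test.

    ``coords`` is (n, 2) population centroids in km; the Euclidean distance
    matrix is tested against the genetic matrix.
    """
    coords = np.asarray(coords, dtype=float)
    D = squareform(pdist(coords))
    return mantel(genetic, D, n_perm=n_perm, seed=seed)


def rank_layers(genetic, layer_matrices: dict[str, np.ndarray],
                conditioning=None, n_perm: int = 9999,
                seed: int | None = None) -> pd.DataFrame:
    """Tables-4-6-style report: Mantel r² and p per layer, sorted by r².

    With ``conditioning`` a partial Mantel is run against each layer.
    """
    rows = []
    for name, M in layer_matrices.items():
        if conditioning is None:
            res = mantel(genetic, M, n_perm=n_perm, seed=seed)
        else:
            res = partial_mantel(genetic, M, conditioning, n_perm=n_perm,
                                 seed=seed)
        rows.append((name, res.r, res.r2, res.p))
    df = pd.DataFrame(rows, columns=["layer", "r", "r2", "p"])
    return df.sort_values("r2", ascending=False).reset_index(drop=True)
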