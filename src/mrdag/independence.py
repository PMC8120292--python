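"""Marginal and conditional independence tests feeding the skeleton search.

Continuous data are handled through Pearson (or robust) correlation with the
Fisher z-transformation test of partial correlation; discrete data through the
G^2 likelihood-ratio test.  A :class:`SufficientStat` bundles whatever the
tests need: a correlation matrix plus sample size for Gaussian data, or the
raw categorical matrix for discrete data.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import GENOTYPE


class CollinearityError(np.linalg.LinAlgError):
    """Conditioning set makes the correlation submatrix singular."""


@dataclasses.dataclass
class SufficientStat:
    """Sufficient statistics for the independence tests.

    ``R`` is a symmetric correlation matrix with unit diagonal, ``n`` the
    sample count.  ``kind`` selects the test family: ``"gaussian"`` uses
    Fisher-z tests on (partial) correlations, ``"discrete"`` uses G^2 tests on
    the retained raw ``data``.
    """

    R: np.ndarray
    n: int
    labels: tuple[str, ...]
    kinds: tuple[str, ...]
    kind: str = "gaussian"
    data: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.labels)
        if self.R.shape != (p, p):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.R)) > 1 + 1e-8:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if self.kind not in ("gaussian", "discrete"):
            raise ValueError(f"unknown data kind {self.kind!r}")
        if self.kind == "discrete" and self.data is None:
            raise ValueError("discrete sufficient statistics require raw data")

    @classmethod
    def from_data(
        cls,
        data: pd.DataFrame | np.ndarray,
        labels: Sequence[str] | None = None,
        kinds: Sequence[str] | None = None,
        kind: str = "gaussian",
        corr: str = "pearson",
    ) -> "SufficientStat":
        """Build sufficient statistics from a samples x variables matrix.

        ``corr`` selects ``"pearson"`` or ``"robust"`` correlation for
        Gaussian data.  With robust correlation and genotype columns present,
        reweighting is applied to the phenotype block only; genotype-anything
        correlations stay plain Pearson.
        """
        if isinstance(data, pd.DataFrame):
            labels = labels or tuple(str(c) for c in data.columns)
            X = data.to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            labels = labels or tuple(f"X{i+1}" for i in range(X.shape[1]))
        labels = tuple(labels)
        kinds = tuple(kinds) if kinds is not None else ("phenotype",) * len(labels)
        n = X.shape[0]
        weights = None
        if kind == "discrete":
            R = np.eye(len(labels))
            return cls(R, n, labels, kinds, kind="discrete", data=X.astype(int))
        if corr == "pearson":
            R = _pearson(X)
        elif corr == "robust":
            R = _pearson(X)
            pheno = [i for i, k in enumerate(kinds) if k != GENOTYPE]
            R_rob, weights = robust_correlation(X[:, pheno])
            R[np.ix_(pheno, pheno)] = R_rob
        else:
            raise ValueError(f"unknown correlation estimator {corr!r}")
        return cls(R, n, labels, kinds, kind="gaussian", weights=weights)

    def reorder(self, new_labels: Sequence[str]) -> "SufficientStat":
        idx = [self.labels.index(l) for l in new_labels]
        return SufficientStat(
            self.R[np.ix_(idx, idx)],
            self.n,
            tuple(new_labels),
            tuple(self.kinds[i] for i in idx),
            kind=self.kind,
            data=None if self.data is None else self.data[:, idx],
            weights=self.weights,
        )


def _pearson(X: np.ndarray) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    return np.clip(np.atleast_2d(R), -1.0, 1.0)


# -- partial correlation and Fisher z --------------------------------------


def partial_correlation(R: np.ndarray, i: int, j: int, S: Sequence[int]) -> float:
    """Partial correlation of variables i and j given the set S.

    Computed from the precision matrix of the correlation submatrix on
    {i, j} union S: rho_{ij.S} = -P_ij / sqrt(P_ii P_jj).
    """
    S = list(S)
    if i in S or j in S or i == j:
        raise ValueError("conditioning set must exclude i and j")
    if not S:
        return float(R[i, j])
    idx = [i, j] + S
    sub = np.asarray(R, dtype=float)[np.ix_(idx, idx)]
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(
            f"singular correlation submatrix for ({i}, {j}) given {S}"
        ) from exc
    denom = P[0, 0] * P[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise CollinearityError(
            f"degenerate precision matrix for ({i}, {j}) given {S}"
        )
    return float(np.clip(-P[0, 1] / np.sqrt(denom), -1.0, 1.0))


def fisher_z_pvalue(rho: float, n: int, s_size: int) -> float:
    """Two-sided p-value of the Fisher z test at partial correlation ``rho``.

    The statistic is sqrt(n - |S| - 3) * |atanh(rho)| against a standard
    normal.  A correlation of +/-1 yields p = 0 (degenerate statistic).
    """
    dof = n - s_size - 3
    if dof < 1:
        raise ValueError(f"need n - |S| - 3 >= 1 (n={n}, |S|={s_size})")
    if abs(rho) >= 1.0:
        warnings.warn("degenerate |rho| = 1 in Fisher z test; returning p = 0")
        return 0.0
    z = np.sqrt(dof) * abs(np.arctanh(rho))
    return float(2.0 * stats.norm.sf(z))


def fisher_z_test(R: np.ndarray, n: int, i: int, j: int, S: Sequence[int]) -> float:
    """Fisher-z test of i independent of j given S; returns the p-value."""
    rho = partial_correlation(R, i, j, S)
    return fisher_z_pvalue(rho, n, len(S))


# -- G^2 test for discrete data ---------------------------------------------


def g_square_test(
    data: np.ndarray, i: int, j: int, S: Sequence[int]
) -> tuple[float, float, int]:
    """G^2 likelihood-ratio test of independence of columns i and j given S.

    Strata are the joint levels of the conditioning columns; within each
    stratum G^2 = 2 sum O log(O/E) with E from the stratum margins, and the
    stratum statistics add up.  Degrees of freedom are
    (L_i - 1)(L_j - 1) prod_k L_k with level counts taken from the full data.
    Returns (p, G2, df).
    """
    X = np.asarray(data)
    S = list(S)
    levels_i = np.unique(X[:, i])
    levels_j = np.unique(X[:, j])
    df = (len(levels_i) - 1) * (len(levels_j) - 1)
    for k in S:
        df *= len(np.unique(X[:, k]))
    if df <= 0:
        warnings.warn("G^2 test with zero degrees of freedom; returning p = 1")
        return 1.0, 0.0, 0
    if S:
        strata = np.unique(X[:, S], axis=0)
        masks = [(X[:, S] == s).all(axis=1) for s in strata]
    else:
        masks = [np.ones(X.shape[0], dtype=bool)]
    g2 = 0.0
    for mask in masks:
        sub = X[mask]
        if sub.shape[0] == 0:
            continue  # empty stratum: skipped
        obs = np.zeros((len(levels_i), len(levels_j)))
        for a, li in enumerate(levels_i):
            for b, lj in enumerate(levels_j):
                obs[a, b] = np.sum((sub[:, i] == li) & (sub[:, j] == lj))
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        tot = obs.sum()
        exp = row * col / tot
        nz = (obs > 0) & (exp > 0)
        g2 += 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    p = float(stats.chi2.sf(g2, df))
    return p, g2, df


# -- robust correlation ------------------------------------------------------


def robust_correlation(
    data: np.ndarray,
    c_quantile: float = 0.999,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust correlation matrix with per-sample weights in [0, 1].

    Iteratively reweighted location/scatter estimation: each iteration
    computes squared Mahalanobis distances under the current estimates and
    assigns Tukey-biweight weights w = (1 - d^2/c^2)^2 for d^2 < c^2 (0
    beyond), with c^2 the ``c_quantile`` chi-square quantile at p degrees of
    freedom.  Gross outliers end up with weights near 0 and contribute almost
    nothing to the correlation estimate.

    Returns (R_robust, weights).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D samples x variables matrix")
    n, p = X.shape
    if p == 0:
        return np.zeros((0, 0)), np.ones(n)
    if n < p + 2:
        raise ValueError(f"robust correlation needs n >= p + 2 (n={n}, p={p})")
    c2 = stats.chi2.ppf(c_quantile, df=p)
    mu = np.median(X, axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    w = np.ones(n)
    for _ in range(max_iter):
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(cov)
        diff = X - mu
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        u = np.clip(d2 / c2, 0.0, None)
        w = np.where(u < 1.0, (1.0 - u) ** 2, 0.0)
        sw = w.sum()
        if sw <= p + 1:
            # nearly all mass rejected; fall back to the least extreme points
            keep = np.argsort(d2)[: max(p + 2, n // 2)]
            w = np.zeros(n)
            w[keep] = 1.0
            sw = w.sum()
        mu_new = (w[:, None] * X).sum(axis=0) / sw
        diff = X - mu_new
        cov_new = (w[:, None] * diff).T @ diff / sw
        shift = max(
            np.max(np.abs(mu_new - mu)), np.max(np.abs(cov_new - cov))
        )
        mu, cov = mu_new, cov_new
        if shift < tol:
            break
    sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    R = cov / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0), w
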