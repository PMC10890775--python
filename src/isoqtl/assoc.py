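"""Per-SNP association statistics and isoform aggregation rules.

Every test here answers, for one cis-SNP and one gene with m isoforms,
"is the SNP associated with any isoform?":

* simple OLS per isoform followed by p-value aggregation (Fisher's method,
  the Cauchy combination test / ACAT, or the naive minimum);
* a multivariate general linear model test (Wilks' lambda with Bartlett's
  chi-squared approximation);
* a multiple regression of the SNP on all isoforms followed by a nested
  F-test;
* gene-level collapses (sum / mean / first principal component) tested with
  simple OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "IsoformPvalueBlock",
    "MultivariateTestResult",
    "P_FLOOR",
    "simple_ols",
    "isoform_pvalue_block",
    "aggregate_fisher",
    "aggregate_cauchy",
    "aggregate_min",
    "wilks_bartlett_test",
    "ftest_multiple_regression",
    "gene_level_phenotype",
]

# smallest p-value reported anywhere; keeps log p finite
P_FLOOR = 1e-300


@dataclass
class IsoformPvalueBlock:
    """Two-sided OLS p-values and slopes for every (isoform, variant) pair
    of one gene; ``valid`` flags testable (non-monomorphic) variants."""

    gene_id: str
    pvals: np.ndarray   # (m isoforms x s variants)
    betas: np.ndarray
    valid: np.ndarray   # (s,) bool


@dataclass
class MultivariateTestResult:
    statistic: float
    df: tuple
    pvalue: float
    test: str


def _t_sf2(t: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from a t statistic, floored at P_FLOOR."""
    p = 2.0 * special.stdtr(df, -np.abs(t))
    return np.clip(p, P_FLOOR, 1.0)


def simple_ols(x: np.ndarray, y: np.ndarray, df_extra: int = 0):
    """Slope, standard error and two-sided p of y regressed on [1, x].

    ``df_extra`` is the number of covariate degrees of freedom already
    consumed upstream (residualization), subtracted from the n-2 residual df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if len(y) != n:
        raise ValueError("x and y must have the same length")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        raise ValueError("monomorphic: var(x) = 0")
    yc = y - y.mean()
    beta = (xc @ yc) / sxx
    rss = yc @ yc - beta * beta * sxx
    df = n - 2 - df_extra
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    if rss <= 0.0:
        return beta, 0.0, P_FLOOR
    se = np.sqrt(rss / df / sxx)
    t = beta / se
    return beta, se, float(_t_sf2(np.asarray(t), df))


def isoform_pvalue_block(gene_id: str, Y: np.ndarray, X: np.ndarray,
                         valid: np.ndarray | None = None,
                         df_extra: int = 0) -> IsoformPvalueBlock:
    """All simple-OLS p-values of a gene: entry (i, j) tests isoform i
    against variant j.  Vectorized; agrees with looped :func:`simple_ols`.

    Y is (m x n), X is (n x s).  Monomorphic variants are excluded via the
    ``valid`` mask (computed from X when not supplied) and carry NaN.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if Y.shape[1] != n:
        raise ValueError("sample dimensions of Y and X disagree")
    Xc = X - X.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    if valid is None:
        valid = sxx > 0.0
    else:
        valid = np.asarray(valid, bool) & (sxx > 0.0)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", Yc, Yc)
    sxy = Yc @ Xc                                 # (m x s)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy[:, None] - beta * sxy
        df = n - 2 - df_extra
        tstat = beta * np.sqrt(np.clip(sxx / (rss / df), 0.0, np.inf))
        p = _t_sf2(tstat, df)
    p[:, ~valid] = np.nan
    beta[:, ~valid] = np.nan
    p[np.isnan(p) & valid[None, :]] = P_FLOOR     # perfect fits: rss == 0
    return IsoformPvalueBlock(gene_id, p, beta, valid)


# ---------------------------------------------------------------------------
# p-value aggregation


def aggregate_fisher(p: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Fisher's method: survival of chi2_{2k} at -2 * sum(log p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped for Fisher aggregation")
        p = np.clip(p, P_FLOOR, 1.0)
    if axis is None:
        p = p.ravel()
        axis = 0
    k = p.shape[axis]
    stat = -2.0 * np.log(p).sum(axis=axis)
    return stats.chi2.sf(stat, 2 * k)


def cauchy_statistic(p: np.ndarray, weights: np.ndarray | None = None,
                     axis: int | None = None) -> np.ndarray:
    """T = sum_i w_i * tan((0.5 - p_i) * pi) with weights summing to 1.

    For p below ~1e-15 the tangent overflows in double precision; the
    standard ACAT approximation tan((0.5 - p) pi) ~ 1/(p pi) is used there.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if axis is None:
        p = p.ravel()
        axis = 0
    p = np.clip(p, P_FLOOR, 1.0 - 1e-16)
    k = p.shape[axis]
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    shape = [1] * p.ndim
    shape[axis] = k
    w = w.reshape(shape)
    small = p < 1e-15
    terms = np.where(small, 1.0 / (np.where(small, p, 1.0) * np.pi),
                     np.tan((0.5 - p) * np.pi))
    return (w * terms).sum(axis=axis)


def aggregate_cauchy(p: np.ndarray, weights: np.ndarray | None = None,
                     axis: int | None = None) -> np.ndarray:
    """Cauchy combination test (ACAT): p = 1/2 - arctan(T)/pi."""
    t0 = cauchy_statistic(p, weights, axis)
    big = t0 > 1e15
    with np.errstate(divide="ignore"):
        out = np.where(big, 1.0 / (np.where(big, t0, 1.0) * np.pi),
                       0.5 - np.arctan(t0) / np.pi)
    return np.clip(out, P_FLOOR, 1.0 - 1e-16) if np.ndim(out) else float(np.clip(out, P_FLOOR, 1.0 - 1e-16))


def aggregate_min(p: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Minimum p-value, with no multiplicity correction.

    Deliberately naive: used after per-isoform permutation adjustment this
    rule calls a gene significant if any isoform is, which inflates the
    gene-level FDR.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if axis is None:
        return float(p.min())
    return p.min(axis=axis)


# ---------------------------------------------------------------------------
# multivariate tests


def wilks_bartlett_test(x: np.ndarray, Y: np.ndarray) -> MultivariateTestResult:
    """Wilks' lambda test of the multivariate regression Y ~ 1 + x against
    the intercept-only model, with Bartlett's chi-squared approximation.

    Y is (n x m).  The ratio |Sigma_hat| / |Sigma_hat_i| of residual
    cross-product determinants gives Lambda^{2/n}; the Bartlett statistic
    -(n - 2 - m/2) * log(ratio) is approximately chi2 with m df.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    if n <= m + 2:
        raise ValueError("need n > m + 2 samples")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        raise ValueError("monomorphic: var(x) = 0")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    S_i = Yc.T @ Yc                    # n * Sigma_hat_i
    u = Yc.T @ xc / np.sqrt(sxx)
    sign_i, logdet_i = np.linalg.slogdet(S_i)
    if sign_i <= 0 or not np.isfinite(logdet_i):
        raise ValueError("degenerate covariance: collinear isoforms")
    # matrix determinant lemma: |S_i - u u^T| / |S_i| = 1 - u^T S_i^{-1} u
    ratio = 1.0 - u @ np.linalg.solve(S_i, u)
    ratio = float(np.clip(ratio, P_FLOOR, 1.0))
    stat = -(n - 2.0 - m / 2.0) * np.log(ratio)
    assert stat >= -1e-9
    p = float(stats.chi2.sf(stat, m))
    return MultivariateTestResult(float(stat), (m,), max(p, P_FLOOR), "wilks_bartlett")


def ftest_multiple_regression(x: np.ndarray, Y: np.ndarray) -> MultivariateTestResult:
    """Nested F-test of the multiple regression x ~ 1 + Y against x ~ 1.

    The SNP dosage is the response and the m isoforms the predictors;
    F = ((RSS_i - RSS_f)/m) / (RSS_f/(n - m - 1)) ~ F(m, n - m - 1).
    Collinear isoform columns are dropped with a warning and the df adjusted.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    if n <= m + 1:
        raise ValueError("need n > m + 1 samples")
    design = np.column_stack([np.ones(n), Y])
    q, r, piv = _qr_drop_collinear(design)
    kept = q.shape[1]
    if kept - 1 < m:
        warnings.warn("collinear isoforms dropped from F-test design")
    m_eff = kept - 1
    if m_eff == 0:
        return MultivariateTestResult(0.0, (0, n - 1), 1.0, "f_test")
    xc = x - x.mean()
    rss_i = float(xc @ xc)
    proj = q.T @ x
    rss_f = float(x @ x - proj @ proj)
    df2 = n - m_eff - 1
    if rss_f <= 0.0:
        return MultivariateTestResult(np.inf, (m_eff, df2), P_FLOOR, "f_test")
    f = ((rss_i - rss_f) / m_eff) / (rss_f / df2)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, m_eff, df2))
    return MultivariateTestResult(float(f), (m_eff, df2), max(p, P_FLOOR), "f_test")


def _qr_drop_collinear(design: np.ndarray, tol: float = 1e-10):
    """Orthonormal basis of the design's column space, dropping collinear
    columns (pivoted via scipy QR)."""
    from scipy.linalg import qr

    q, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    return q[:, :rank], r[:rank], piv[:rank]


# ---------------------------------------------------------------------------
# gene-level collapses


def gene_level_phenotype(Y: np.ndarray, mode: str = "sum") -> np.ndarray:
    """Collapse an (m x n) isoform matrix to one phenotype per sample.

    ``sum`` and ``mean`` differ only by the constant 1/m and give identical
    test p-values.  ``pca1`` returns the sample scores on the first
    principal component of the row-centered isoform matrix, with the sign
    fixed so the largest-magnitude loading is positive.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m = Y.shape[0]
    if mode == "sum":
        return Y.sum(axis=0)
    if mode == "mean":
        return Y.mean(axis=0)
    if mode == "pca1":
        Yc = Y - Y.mean(axis=1, keepdims=True)
        if m == 1:
            return Yc[0]
        u, s, vt = np.linalg.svd(Yc, full_matrices=False)
        loading = u[:, 0]
        sign = np.sign(loading[np.argmax(np.abs(loading))]) or 1.0
        return sign * s[0] * vt[0]
    raise ValueError(f"unknown mode {mode!r}")
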