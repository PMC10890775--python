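"""Beta-approximated permutation adjustment and genome-wide FDR.

Each "pass" corrects one gene's best nominal p-value for the number of
correlated cis-SNPs (and, for isoform-aware passes, isoforms) that were
searched: the observed minimum p is compared against R permutation minima,
whose tail is approximated by a maximum-likelihood Beta(a, b) fit so that
adjusted p-values far below 1/(R+1) remain estimable.  Within a replicate
one shared sample permutation is applied to every isoform of the gene,
preserving the inter-isoform correlation under the null.

Across genes, Storey's q-value turns the adjusted p-values into FDR calls.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .assoc import (
    P_FLOOR,
    _t_sf2,
    aggregate_cauchy,
    aggregate_fisher,
    _qr_drop_collinear,
)

__all__ = [
    "BetaNullFit",
    "GeneResult",
    "gene_rng",
    "direct_perm_pvalue",
    "fit_beta_mle",
    "beta_adjust",
    "perm_pass_single",
    "perm_pass_grouped",
    "perm_pass_aggregated",
    "perm_pass_multivariate",
    "qtltools_iso_aggregate",
    "estimate_pi0",
    "storey_qvalue",
    "call_egenes",
]

MIN_PERMUTATIONS = 50


@dataclass
class BetaNullFit:
    """Beta(a, b) approximation to a permutation null of minimum p-values."""

    a: float
    b: float
    R: int
    null_min_pvals: np.ndarray
    converged: bool = True


@dataclass
class GeneResult:
    """Per-gene output of one mapping method."""

    gene_id: str
    method: str
    best_variant: object = None
    best_isoform: object = None
    p_nominal: float = 1.0
    p_adjusted: float = 1.0
    p_direct: float = 1.0
    q_value: float = np.nan
    n_isoforms: int = 1
    flag: str = ""
    beta_fit: BetaNullFit = field(default=None, repr=False)


def gene_rng(master_seed: int, gene_id: str, salt: int = 0) -> np.random.Generator:
    """Deterministic per-gene random stream, independent of the order in
    which genes are processed."""
    h = zlib.crc32(str(gene_id).encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h, salt])
    return np.random.default_rng(ss)


def _permutations(rng: np.random.Generator, n: int, R: int) -> np.ndarray:
    """(R x n) array of sample permutations."""
    return np.argsort(rng.random((R, n)), axis=1)


# ---------------------------------------------------------------------------
# beta machinery


def direct_perm_pvalue(r: int, R: int) -> float:
    """(r + 1) / (R + 1): the direct permutation p-value when r of R
    permutation statistics beat the observed one."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if r < 0 or r > R:
        raise ValueError("need 0 <= r <= R")
    return (r + 1) / (R + 1)


def fit_beta_mle(null_pvals: np.ndarray, max_iter: int = 1000,
                 tol: float = 1e-8) -> BetaNullFit:
    """Maximum-likelihood Beta(a, b) fit to permutation minimum p-values.

    Newton iterations on the two shape parameters (the log-likelihood
    depends on the data only through mean(log p) and mean(log(1-p))),
    initialized at the method-of-moments estimate; falls back to the
    method of moments with a warning if Newton does not converge.
    """
    p = np.asarray(null_pvals, dtype=float)
    R = len(p)
    if R < MIN_PERMUTATIONS:
        raise ValueError(f"need at least {MIN_PERMUTATIONS} permutations")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("null p-values must lie in (0, 1]")
    if np.ptp(p) == 0:
        raise ValueError("zero variance in permutation null")
    pc = np.clip(p, 1e-300, 1.0 - 1e-12)
    mean, var = pc.mean(), pc.var()
    c = mean * (1.0 - mean) / var - 1.0
    if c > 0:
        a, b = max(mean * c, 1e-3), max((1.0 - mean) * c, 1e-3)
    else:
        a, b = 1.0, 1.0
    a_mom, b_mom = a, b
    s1 = np.log(pc).mean()
    s2 = np.log1p(-pc).mean()
    converged = False
    for _ in range(max_iter):
        psi_ab = special.digamma(a + b)
        g = np.array([special.digamma(a) - psi_ab - s1,
                      special.digamma(b) - psi_ab - s2])
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        tri_ab = special.polygamma(1, a + b)
        H = np.array([[special.polygamma(1, a) - tri_ab, -tri_ab],
                      [-tri_ab, special.polygamma(1, b) - tri_ab]])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # backtrack to stay in the positive quadrant
        scale = 1.0
        while a - scale * step[0] <= 0 or b - scale * step[1] <= 0:
            scale *= 0.5
            if scale < 1e-12:
                break
        a -= scale * step[0]
        b -= scale * step[1]
    if not converged:
        warnings.warn("Beta MLE did not converge; using method of moments")
        a, b = a_mom, b_mom
    return BetaNullFit(float(a), float(b), R, p, converged)


def beta_adjust(p_nominal, fit: BetaNullFit):
    """Adjusted permutation p-value: Beta(a, b) CDF at the nominal p."""
    out = special.betainc(fit.a, fit.b, np.clip(p_nominal, 0.0, 1.0))
    out = np.clip(out, P_FLOOR, 1.0)
    return float(out) if np.ndim(p_nominal) == 0 else out


# ---------------------------------------------------------------------------
# pass plumbing


def _normalize_columns(X: np.ndarray, valid=None):
    """Center columns and scale to unit norm; returns (Xn, valid mask)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    ok = norms > 0
    if valid is not None:
        ok = ok & np.asarray(valid, bool)
    Xn = np.zeros_like(Xc)
    Xn[:, ok] = Xc[:, ok] / norms[ok]
    return Xn, ok


def _corr_to_minp(absr: np.ndarray, df: int, axis=None):
    """Min two-sided OLS p along ``axis`` from |correlations| (monotone:
    the largest |r| attains the smallest p)."""
    rmax = absr if axis is None else absr.max(axis=axis)
    rmax = np.clip(rmax, 0.0, 1.0 - 1e-15)
    t = rmax * np.sqrt(df / (1.0 - rmax * rmax))
    return _t_sf2(t, df)


def _empty_result(gene_id, method, n_isoforms, flag="no_cis_snps") -> GeneResult:
    return GeneResult(gene_id, method, None, None, 1.0, 1.0, 1.0,
                      np.nan, n_isoforms, flag)


def _finalize(gene_id, method, p_obs, null_min, best_variant, best_isoform,
              n_isoforms) -> GeneResult:
    null_min = np.clip(null_min, P_FLOOR, 1.0)
    fit = fit_beta_mle(null_min)
    r = int((null_min <= p_obs).sum())
    return GeneResult(
        gene_id, method, best_variant, best_isoform,
        float(p_obs), beta_adjust(float(p_obs), fit),
        direct_perm_pvalue(r, len(null_min)), np.nan, n_isoforms, "", fit,
    )


def _ids(variant_ids, j):
    return j if variant_ids is None else variant_ids[j]


# ---------------------------------------------------------------------------
# the passes


def perm_pass_single(gene_id, y, X, R=1000, rng=None, variant_ids=None,
                     valid=None, method="qtl-single") -> GeneResult:
    """Permutation pass for one phenotype: the observed statistic is the
    minimum simple-OLS p over cis-variants; the null replays it on R
    permutations of the phenotype's sample order."""
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xn, ok = _normalize_columns(X, valid)
    if not ok.any():
        return _empty_result(gene_id, method, 1)
    yc = y - y.mean()
    nrm = np.sqrt(yc @ yc)
    if nrm == 0:
        return _empty_result(gene_id, method, 1, flag="constant_phenotype")
    yn = yc / nrm
    perms = _permutations(rng, n, R)
    rows = np.vstack([yn[None, :], yn[perms]])       # (R+1, n)
    C = np.abs(rows @ Xn)                            # (R+1, s)
    C[:, ~ok] = 0.0
    df = n - 2
    j = int(np.argmax(C[0]))
    p_obs = float(_corr_to_minp(C[0, j], df))
    null_min = _corr_to_minp(C[1:], df, axis=1)
    res = _finalize(gene_id, method, p_obs, null_min, _ids(variant_ids, j),
                    None, 1)
    return res


def perm_pass_grouped(gene_id, Y, X, R=1000, rng=None, variant_ids=None,
                      isoform_ids=None, valid=None,
                      method="qtl-grpbest") -> GeneResult:
    """QTLtools-style grouped pass: the search space is all (isoform,
    variant) pairs; each null replicate applies ONE shared sample
    permutation to all isoforms before re-taking the pair minimum."""
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = Y.shape
    Xn, ok = _normalize_columns(X, valid)
    if not ok.any():
        return _empty_result(gene_id, method, m)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    nrm = np.sqrt(np.einsum("ij,ij->i", Yc, Yc))
    if (nrm == 0).all():
        return _empty_result(gene_id, method, m, flag="constant_phenotype")
    Yn = np.zeros_like(Yc)
    live = nrm > 0
    Yn[live] = Yc[live] / nrm[live, None]
    perms = _permutations(rng, n, R)
    C0 = np.abs(Yn @ Xn)                              # (m, s)
    C0[:, ~ok] = 0.0
    df = n - 2
    # variant-major flatten: ties resolve to smallest variant, then isoform
    flat = np.argmax(C0.T.ravel())
    j, i = divmod(int(flat), m)
    p_obs = float(_corr_to_minp(C0[i, j], df))
    stack = Yn[:, perms]                              # (m, R, n)
    Cn = np.abs(np.einsum("mrn,ns->rms", stack, Xn))
    Cn[:, :, ~ok] = 0.0
    null_min = _corr_to_minp(Cn.reshape(R, -1), df, axis=1)
    return _finalize(gene_id, method, p_obs, null_min, _ids(variant_ids, j),
                     i if isoform_ids is None else isoform_ids[i], m)


_AGGREGATORS = {
    "fisher": lambda P, w: aggregate_fisher(P, axis=1),
    "cauchy": lambda P, w: aggregate_cauchy(P, w, axis=1),
    "min": lambda P, w: P.min(axis=1),
}


def perm_pass_aggregated(gene_id, Y, X, aggregator="fisher", R=1000, rng=None,
                         variant_ids=None, valid=None, weights=None,
                         method=None) -> GeneResult:
    """Aggregation-before-permutation pass: per variant the m isoform
    p-values are combined (Fisher / Cauchy / min) into one gene-level p,
    the observed statistic is the minimum over variants, and the null
    replays the whole computation under shared sample permutations."""
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    method = method or f"{aggregator}-perm"
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = Y.shape
    Xn, ok = _normalize_columns(X, valid)
    if not ok.any():
        return _empty_result(gene_id, method, m)
    Xv = Xn[:, ok]
    orig_idx = np.nonzero(ok)[0]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    nrm = np.sqrt(np.einsum("ij,ij->i", Yc, Yc))
    if (nrm == 0).any():
        return _empty_result(gene_id, method, m, flag="constant_phenotype")
    Yn = Yc / nrm[:, None]
    perms = _permutations(rng, n, R)
    stack = np.concatenate([Yn[:, None, :], Yn[:, perms]], axis=1)  # (m, R+1, n)
    C = np.einsum("mrn,ns->rms", stack, Xv)          # (R+1, m, s)
    df = n - 2
    absr = np.clip(np.abs(C), 0.0, 1.0 - 1e-15)
    t = absr * np.sqrt(df / (1.0 - absr * absr))
    P = _t_sf2(t, df)                                # (R+1, m, s)
    G = np.clip(_AGGREGATORS[aggregator](P, weights), P_FLOOR, 1.0)  # (R+1, s)
    j = int(np.argmin(G[0]))
    p_obs = float(G[0, j])
    null_min = G[1:].min(axis=1)
    return _finalize(gene_id, method, p_obs, null_min,
                     _ids(variant_ids, orig_idx[j]), None, m)


def perm_pass_multivariate(gene_id, Y, X, test="ftest", R=1000, rng=None,
                           variant_ids=None, valid=None,
                           method=None) -> GeneResult:
    """Permutation pass over per-variant multivariate tests (nested F-test
    of SNP ~ isoforms, or Wilks-Bartlett), min over variants."""
    if test not in ("ftest", "wilks"):
        raise ValueError(f"unknown multivariate test {test!r}")
    method = method or test
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = Y.shape
    X = np.asarray(X, dtype=float)
    sx = X.std(axis=0) > 0
    ok = sx if valid is None else sx & np.asarray(valid, bool)
    if not ok.any():
        return _empty_result(gene_id, method, m)
    Xv = X[:, ok]
    orig_idx = np.nonzero(ok)[0]
    perms = _permutations(rng, n, R)

    if test == "ftest":
        design = np.column_stack([np.ones(n), Y.T])
        Q, _, _ = _qr_drop_collinear(design)
        k = Q.shape[1]
        m_eff = k - 1
        if m_eff == 0:
            return _empty_result(gene_id, method, m, flag="constant_phenotype")
        df2 = n - m_eff - 1
        sx2 = np.einsum("ij,ij->j", Xv, Xv)
        rss_i = sx2 - n * Xv.mean(axis=0) ** 2
        idx = np.vstack([np.arange(n)[None, :], perms])   # (R+1, n)
        QT = Q[idx]                                       # (R+1, n, k)
        proj = QT.transpose(0, 2, 1).reshape(-1, n) @ Xv  # ((R+1)k, s)
        proj = proj.reshape(R + 1, k, len(orig_idx))
        rss_f = np.clip(sx2[None, :] - np.einsum("rks,rks->rs", proj, proj),
                        1e-300, None)
        F = ((rss_i[None, :] - rss_f) / m_eff) / (rss_f / df2)
        F = np.clip(F, 0.0, None)
        j = int(np.argmax(F[0]))
        p_obs = float(max(stats.f.sf(F[0, j], m_eff, df2), P_FLOOR))
        null_min = np.clip(stats.f.sf(F[1:].max(axis=1), m_eff, df2),
                           P_FLOOR, 1.0)
        return _finalize(gene_id, method, p_obs, null_min,
                         _ids(variant_ids, orig_idx[j]), None, m)

    # wilks
    if n <= m + 2:
        raise ValueError("need n > m + 2 samples for Wilks-Bartlett")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    S = Yc @ Yc.T
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("degenerate covariance: collinear isoforms")
    S_inv = np.linalg.inv(S)
    Xn, _ = _normalize_columns(Xv)
    stack = np.concatenate([Yc[:, None, :], Yc[:, perms]], axis=1)  # (m, R+1, n)
    V = np.einsum("mrn,ns->rms", stack, Xn)           # (R+1, m, s)
    ratio = 1.0 - np.einsum("ras,ab,rbs->rs", V, S_inv, V)
    ratio = np.clip(ratio, P_FLOOR, 1.0)
    const = n - 2.0 - m / 2.0
    stat = -const * np.log(ratio)
    j = int(np.argmax(stat[0]))
    p_obs = float(max(stats.chi2.sf(stat[0, j], m), P_FLOOR))
    null_min = np.clip(stats.chi2.sf(stat[1:].max(axis=1), m), P_FLOOR, 1.0)
    return _finalize(gene_id, method, p_obs, null_min,
                     _ids(variant_ids, orig_idx[j]), None, m)


def qtltools_iso_aggregate(results, aggregator="fisher",
                           weights=None, method=None) -> GeneResult:
    """Aggregation-after-permutation: combine the per-isoform adjusted
    p-values (each from a single-phenotype pass) into one gene-level p."""
    results = list(results)
    if not results:
        raise ValueError("no per-isoform results to aggregate")
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    method = method or f"{aggregator}-iso"
    p = np.array([r.p_adjusted for r in results], dtype=float)
    if aggregator == "fisher":
        gene_p = float(aggregate_fisher(p))
    elif aggregator == "cauchy":
        gene_p = float(aggregate_cauchy(p, weights))
    else:
        gene_p = float(p.min())
    best = results[int(np.argmin(p))]
    return GeneResult(
        best.gene_id, method, best.best_variant, best.best_isoform,
        float(min(r.p_nominal for r in results)),
        float(np.clip(gene_p, P_FLOOR, 1.0)), np.nan, np.nan, len(results), "",
    )


# ---------------------------------------------------------------------------
# genome-wide FDR


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate pi0.

    pi0(lambda) = #{p > lambda} / (G (1 - lambda)) on the grid
    {0.05, ..., 0.95}, smoothed by a cubic least-squares fit extrapolated
    to lambda -> 1 and clamped to (0, 1].  Falls back to the conservative
    pi0 = 1 when there are fewer than 100 tests or when no p-value exceeds
    the top of the grid (the estimator then carries no information).
    """
    p = np.asarray(p, dtype=float)
    G = len(p)
    if G < 1:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lam_max = float(np.max(lambdas))
    if G < 100:
        warnings.warn("fewer than 100 tests: using conservative pi0 = 1")
        pi0 = 1.0
    elif not (p > lam_max).any():
        # no p-values beyond the top of the lambda grid: the null-proportion
        # estimator has no information near 1 (e.g. uncorrected minimum
        # aggregation shifts every p downward); fall back to the
        # conservative pi0 = 1, i.e. plain Benjamini-Hochberg
        warnings.warn("no p-values above the lambda grid: using pi0 = 1")
        pi0 = 1.0
    else:
        pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_lam, 3)
        pi0 = float(np.polyval(coef, 1.0))
        if pi0 <= 0.0:
            pi0 = float(pi0_lam[-1])        # plug-in at the top grid point
        pi0 = min(max(pi0, 1e-8), 1.0)
    return pi0


def storey_qvalue(p: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values: pi0-scaled step-up adjustment,
    monotone nondecreasing in p (see :func:`estimate_pi0` for pi0)."""
    p = np.asarray(p, dtype=float)
    G = len(p)
    pi0 = estimate_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * G * p[order] / np.arange(1, G + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(G)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_egenes(q: np.ndarray, threshold: float = 0.10) -> np.ndarray:
    """Boolean eGene calls at the q-value threshold."""
    return np.asarray(q, dtype=float) <= threshold
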