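"""Synthetic genotypes and isoform expression with ground truth.

Expression follows the generative model

    Y = sum_j beta_j x_j^T + U + eps

for each gene: m isoform rows, n sample columns.  The k causal SNP dosage
columns x_j are standardized, so the per-SNP variance fractions sigma_gj^2
(summing to the gene's cis heritability sigma_g^2) are directly the
variance explained.  beta_j ~ N(0, sigma_gj^2 * Phi_j) couples the effect
of one SNP across isoforms; Phi_j's off-diagonal signs are negative with
probability ``negpct``, which makes effects cancel when isoforms are
summed.  U is matrix normal with isoform covariance V*sigma_h and sample
covariance W*sigma_h (entry variance sigma_h^2), modelling shared non-cis
effects such as trans-regulation or environment; eps is iid noise with
variance sigma_e^2 = 1 - sigma_g^2 - sigma_h^2, so isoform variances
average to 1.

Genes are declared null (sigma_g^2 = 0) with probability ``null_fraction``
so both FDR and power can be scored against the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, IsoformExpressionSet
from .perm import gene_rng

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "make_correlation",
    "block_exchangeable",
    "simulate_gene",
    "simulate_study",
    "write_vcf",
    "write_truth",
    "read_truth",
]


@dataclass
class SimConfig:
    """Study-level simulation settings (defaults match the benchmark
    conditions: 87 diploid samples, 4 isoforms per gene, 200 cis-SNPs in a
    100 kb window, half the genes null)."""

    n: int = 87
    genes: int = 400
    m: int = 4
    snps: int = 200
    window_bp: int = 100_000
    k_choices: tuple = (1, 2, 3)
    sigma_g2: float = 0.05
    sigma_h2: float = 0.0
    negpct: float = 0.5
    null_fraction: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_g2 + self.sigma_h2 > 1.0:
            raise ValueError("sigma_g2 + sigma_h2 must be <= 1")
        if not 0.0 <= self.negpct <= 1.0:
            raise ValueError("negpct must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    is_null: bool
    causal_ids: list
    beta: np.ndarray            # (m x k), zero matrix for null genes
    sigma_gj2: np.ndarray       # per causal SNP, sums to sigma_g2
    sigma_g2: float
    sigma_h2: float
    phi: list = field(default=None, repr=False)   # per-SNP Phi_j
    V: np.ndarray = field(default=None, repr=False)
    W: np.ndarray = field(default=None, repr=False)


def simulate_genotypes(n: int, s: int, rng, maf_range=(0.05, 0.5),
                       ld_rho: float = 0.7, start_pos: int = 1,
                       span_bp: int = 200_000, chrom: str = "chr1",
                       prefix: str = "var") -> GenotypeMatrix:
    """Diploid dosages with AR(1) linkage disequilibrium.

    Each of the 2n haplotypes is a stationary AR(1) Gaussian series with
    lag-one correlation ``ld_rho``, thresholded per site at the quantile of
    a MAF drawn uniformly from ``maf_range``; the dosage is the haplotype
    sum.  Positions are evenly spaced over ``span_bp`` from ``start_pos``.
    """
    rng = np.random.default_rng(rng)
    maf = rng.uniform(*maf_range, size=s)
    z = np.empty((2 * n, s))
    z[:, 0] = rng.standard_normal(2 * n)
    innov = rng.standard_normal((2 * n, s))
    scale = np.sqrt(1.0 - ld_rho ** 2)
    for j in range(1, s):
        z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j]
    hap = (z < stats.norm.ppf(maf)[None, :]).astype(float)
    dosage = hap[:n] + hap[n:]
    pos = start_pos + np.round(np.linspace(0, span_bp - 1, s)).astype(np.int64)
    ids = [f"{prefix}_{j}" for j in range(s)]
    return GenotypeMatrix(dosage, ids, [chrom] * s, pos,
                          [f"s{i:04d}" for i in range(n)])


def make_correlation(m: int, negpct: float, rng,
                     max_iter: int = 200) -> np.ndarray:
    """Random m x m correlation matrix with off-diagonal magnitudes
    Uniform(0.2, 0.8), each negative with probability ``negpct``, projected
    to the nearest positive semidefinite correlation matrix by alternating
    projections (eigenvalue clipping / unit-diagonal restoration)."""
    rng = np.random.default_rng(rng)
    if m == 1:
        return np.ones((1, 1))
    mag = rng.uniform(0.2, 0.8, size=(m, m))
    sign = np.where(rng.random((m, m)) < negpct, -1.0, 1.0)
    C = mag * sign
    C = np.triu(C, 1)
    C = C + C.T + np.eye(m)
    for shrink in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0):
        A = shrink * C + (1.0 - shrink) * np.eye(m)
        for _ in range(max_iter):
            w, v = np.linalg.eigh(A)
            if w.min() >= -1e-10:
                break
            A = (v * np.clip(w, 0.0, None)) @ v.T
            np.fill_diagonal(A, 1.0)
            A = (A + A.T) / 2.0
        if np.linalg.eigvalsh(A).min() >= -1e-10:
            return A
    return np.eye(m)


def block_exchangeable(n: int, n_blocks: int = 4, rho: float = 0.5) -> np.ndarray:
    """Sample covariance W: unit diagonal, correlation ``rho`` within each
    of ``n_blocks`` contiguous sample blocks, zero between blocks."""
    W = np.eye(n)
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        W[a:b, a:b] = rho
    np.fill_diagonal(W, 1.0)
    return W


def _psd_sqrt(A: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(A)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_gene(gene_id: str, X_cis: np.ndarray, cfg: SimConfig, rng,
                  variant_ids=None, W: np.ndarray | None = None,
                  L_W: np.ndarray | None = None):
    """Simulate (Y: m x n, SimTruth) for one gene over its cis genotypes.

    ``X_cis`` is (n x s) dosages.  ``W`` (or its factor ``L_W``) may be
    shared across genes; by default a block-exchangeable W with 4 blocks
    and within-block rho 0.5 is used.
    """
    rng = np.random.default_rng(rng)
    X_cis = np.asarray(X_cis, dtype=float)
    n, s = X_cis.shape
    m = cfg.m
    is_null = bool(rng.random() < cfg.null_fraction)
    sigma_g2 = 0.0 if is_null else cfg.sigma_g2
    sigma_e2 = 1.0 - sigma_g2 - cfg.sigma_h2
    if sigma_e2 < 0:
        raise ValueError("sigma_g2 + sigma_h2 must be <= 1")

    Y = np.zeros((m, n))
    causal_ids, beta, sg_j, phis = [], np.zeros((m, 0)), np.zeros(0), []
    if not is_null and s > 0:
        sd = X_cis.std(axis=0)
        poly = np.nonzero(sd > 0)[0]
        k = min(int(rng.choice(cfg.k_choices)), len(poly))
        if k > 0:
            causal = rng.choice(poly, size=k, replace=False)
            causal.sort()
            sg_j = sigma_g2 * rng.dirichlet(np.ones(k))
            beta = np.zeros((m, k))
            for j, cj in enumerate(causal):
                phi = make_correlation(m, cfg.negpct, rng)
                phis.append(phi)
                beta[:, j] = _psd_sqrt(phi) @ rng.standard_normal(m) * np.sqrt(sg_j[j])
                xj = (X_cis[:, cj] - X_cis[:, cj].mean()) / sd[cj]
                Y += np.outer(beta[:, j], xj)
            causal_ids = (list(causal) if variant_ids is None
                          else [variant_ids[c] for c in causal])

    V = None
    if cfg.sigma_h2 > 0:
        V = make_correlation(m, 0.5, rng)
        if L_W is None:
            L_W = _psd_sqrt(block_exchangeable(n) if W is None else W)
        Z = rng.standard_normal((m, n))
        Y += np.sqrt(cfg.sigma_h2) * (_psd_sqrt(V) @ Z @ L_W.T)
    if sigma_e2 > 0:
        Y += np.sqrt(sigma_e2) * rng.standard_normal((m, n))

    truth = SimTruth(gene_id, is_null, causal_ids, beta, sg_j,
                     sigma_g2, cfg.sigma_h2, phis, V,
                     W if cfg.sigma_h2 > 0 else None)
    return Y, truth


def simulate_study(cfg: SimConfig):
    """Simulate a whole study: one cis window of genotypes plus one gene
    per locus, fully determined by ``cfg.seed``.

    Returns (IsoformExpressionSet, GenotypeMatrix, list[SimTruth]).  Loci
    are spaced so cis windows never overlap.
    """
    spacing = 10 * cfg.window_bp
    sample_ids = [f"s{i:04d}" for i in range(cfg.n)]
    all_dos, all_ids, all_chrom, all_pos = [], [], [], []
    expr_rows, iso_ids, iso_gene = [], [], []
    iso_chrom, iso_start, iso_end, iso_strand = [], [], [], []
    gene_tss, truths = {}, []
    W = block_exchangeable(cfg.n)
    L_W = _psd_sqrt(W)
    for g in range(cfg.genes):
        gid = f"gene{g:04d}"
        rng = gene_rng(cfg.seed, gid, salt=7)
        tss = spacing * (g + 1)
        gm = simulate_genotypes(
            cfg.n, cfg.snps, rng, cfg.maf_range, cfg.ld_rho,
            start_pos=tss - cfg.window_bp, span_bp=2 * cfg.window_bp,
            prefix=gid,
        )
        Y, truth = simulate_gene(gid, gm.dosages, cfg, rng,
                                 variant_ids=gm.variant_ids, W=W, L_W=L_W)
        all_dos.append(gm.dosages)
        all_ids.append(gm.variant_ids)
        all_chrom.extend(["chr1"] * cfg.snps)
        all_pos.append(gm.pos)
        truths.append(truth)
        gene_tss[gid] = ("chr1", int(tss), "+")
        for i in range(cfg.m):
            iso_ids.append(f"{gid}_iso{i}")
            iso_gene.append(gid)
            iso_chrom.append("chr1")
            iso_start.append(tss - 1)
            iso_end.append(tss + 1000)
            iso_strand.append("+")
        expr_rows.append(Y)
    geno = GenotypeMatrix(np.hstack(all_dos), np.concatenate(all_ids),
                          all_chrom, np.concatenate(all_pos), sample_ids)
    expr = IsoformExpressionSet(
        np.vstack(expr_rows), iso_ids, iso_gene, sample_ids, gene_tss,
        np.asarray(iso_chrom, dtype=object), np.asarray(iso_start, dtype=np.int64),
        np.asarray(iso_end, dtype=np.int64), np.asarray(iso_strand, dtype=object),
    )
    return expr, geno, truths


# ---------------------------------------------------------------------------
# fixture writers


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write dosages as a minimal VCF 4.2 with GT calls (dosages rounded to
    the nearest allele count)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.sample_ids)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(geno.n_variants):
            calls = [gt_map[int(round(d))] for d in geno.dosages[:, j]]
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.variant_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_truth(truths, path: str) -> None:
    rows = [{
        "gene_id": t.gene_id,
        "is_null": int(t.is_null),
        "causal_ids": ",".join(map(str, t.causal_ids)) or "NA",
        "sigma_g2": t.sigma_g2,
        "sigma_h2": t.sigma_h2,
    } for t in truths]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
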