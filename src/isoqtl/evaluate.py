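"""Run registered mapping methods over a study and score FDR / power.

The registry mirrors the method families compared in the benchmark:

==============  ============================================================
qtl-sum/mean    collapse isoforms by sum / mean, single-phenotype pass
qtl-pca1        first principal component of the isoforms, single pass
qtl-grpbest     grouped permutation over all (isoform, variant) pairs
fisher-perm     aggregate isoform p-values per variant (Fisher), then pass
cauchy-perm     as above with the Cauchy combination test
min-perm        as above with the minimum p-value
fisher-iso      single pass per isoform, then Fisher over adjusted p-values
cauchy-iso      as above with the Cauchy combination test
min-iso         as above with the minimum (known to inflate gene-level FDR)
wilks           Wilks-Bartlett multivariate test per variant, then pass
ftest           multiple-regression F-test per variant, then pass
==============  ============================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import perm
from .io import GenotypeMatrix, IsoformExpressionSet, cis_window, testable_variants
from .assoc import gene_level_phenotype
from .perm import (
    GeneResult,
    call_egenes,
    gene_rng,
    perm_pass_aggregated,
    perm_pass_grouped,
    perm_pass_multivariate,
    perm_pass_single,
    qtltools_iso_aggregate,
    storey_qvalue,
)
from .simulate import SimConfig, simulate_study

__all__ = ["METHODS", "MethodScore", "run_method", "score", "grid_experiment"]


def _gene_pass(method, gene_id, Y, X, R, rng, variant_ids, isoform_ids, valid,
               seed):
    if method in ("qtl-sum", "qtl-mean", "qtl-pca1"):
        mode = method.split("-")[1]
        y = gene_level_phenotype(Y, mode)
        res = perm_pass_single(gene_id, y, X, R, rng, variant_ids, valid,
                               method=method)
        res.n_isoforms = Y.shape[0]  # report the gene's size, not the collapse
        return res
    if method == "qtl-grpbest":
        return perm_pass_grouped(gene_id, Y, X, R, rng, variant_ids,
                                 isoform_ids, valid, method=method)
    if method.endswith("-perm"):
        return perm_pass_aggregated(gene_id, Y, X, method[:-5], R, rng,
                                    variant_ids, valid, method=method)
    if method.endswith("-iso"):
        per_iso = []
        for i in range(Y.shape[0]):
            iso_rng = gene_rng(seed, f"{gene_id}:{i}")
            r = perm_pass_single(gene_id, Y[i], X, R, iso_rng, variant_ids,
                                 valid, method=method)
            r.best_isoform = isoform_ids[i] if isoform_ids is not None else i
            per_iso.append(r)
        return qtltools_iso_aggregate(per_iso, method[:-4], method=method)
    if method in ("wilks", "ftest"):
        return perm_pass_multivariate(gene_id, Y, X, method, R, rng,
                                      variant_ids, valid, method=method)
    raise ValueError(f"unknown method {method!r}; registry: {sorted(METHODS)}")


METHODS = (
    "qtl-sum", "qtl-mean", "qtl-pca1", "qtl-grpbest",
    "fisher-perm", "cauchy-perm", "min-perm",
    "fisher-iso", "cauchy-iso", "min-iso",
    "wilks", "ftest",
)


def run_method(method: str, expr: IsoformExpressionSet, geno: GenotypeMatrix,
               R: int = 1000, seed: int = 0, window_bp: int = 100_000,
               fdr_threshold: float = 0.10, maf_min: float = 0.01):
    """Run one registered method over every gene of a study.

    Returns a list of :class:`GeneResult` (gene order = first appearance in
    the expression set) with q-values filled in, plus the boolean eGene
    calls at ``fdr_threshold``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; registry: {sorted(METHODS)}")
    ok_all = testable_variants(geno, maf_min)
    results = []
    for gid in expr.gene_ids:
        Y = expr.gene_expr(gid)
        win = cis_window(gid, expr.gene_tss[gid], geno, window_bp)
        X = geno.dosages[:, win.variant_idx]
        vids = geno.variant_ids[win.variant_idx]
        valid = ok_all[win.variant_idx]
        rng = gene_rng(seed, gid)
        res = _gene_pass(method, gid, Y, X, R, rng, vids,
                         expr.gene_isoform_ids(gid), valid, seed)
        results.append(res)
    q = storey_qvalue(np.array([r.p_adjusted for r in results]))
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    calls = call_egenes(q, fdr_threshold)
    return results, calls


@dataclass
class MethodScore:
    """Empirical FDR and power of one method at one parameter point."""

    method: str
    sigma_g2: float
    sigma_h2: float
    negpct: float
    m: int
    replicate: int
    fdr: float
    power: float
    n_calls: int
    n_true_positives: int


def score(calls: np.ndarray, truths, method: str = "",
          cfg: SimConfig | None = None, replicate: int = 0) -> MethodScore:
    """Score eGene calls against the simulation truth.

    FDR = FP / max(1, FP + TP) (0 when nothing is called); power =
    TP / number of non-null genes.
    """
    calls = np.asarray(calls, dtype=bool)
    is_null = np.array([t.is_null for t in truths], dtype=bool)
    if len(calls) != len(is_null):
        raise ValueError("calls not aligned to truth")
    tp = int((calls & ~is_null).sum())
    fp = int((calls & is_null).sum())
    n_alt = int((~is_null).sum())
    fdr = fp / max(1, fp + tp)
    power = tp / n_alt if n_alt else 0.0
    cfg = cfg or SimConfig()
    return MethodScore(method, cfg.sigma_g2, cfg.sigma_h2, cfg.negpct, cfg.m,
                       replicate, fdr, power, tp + fp, tp)


def grid_experiment(base: SimConfig, methods, vary: dict | None = None,
                    replicates: int = 1, R: int = 500,
                    fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Benchmark methods across a parameter grid.

    ``vary`` maps a SimConfig field name to the values to sweep (one
    parameter varies, the others stay at ``base``); None runs the single
    base point.  Returns a long-format table: method x point x replicate ->
    fdr, power, n_calls.
    """
    points = [{}]
    if vary:
        points = [{name: v} for name, vals in vary.items() for v in vals]
    rows = []
    for rep in range(replicates):
        for overrides in points:
            cfg = SimConfig(**{**_cfg_dict(base), **overrides,
                               "seed": base.seed + 1009 * rep})
            expr, geno, truths = simulate_study(cfg)
            for method in methods:
                _, calls = run_method(method, expr, geno, R=R, seed=cfg.seed,
                                      window_bp=cfg.window_bp,
                                      fdr_threshold=fdr_threshold)
                sc = score(calls, truths, method, cfg, rep)
                rows.append(vars(sc))
    return pd.DataFrame(rows)


def _cfg_dict(cfg: SimConfig) -> dict:
    return {f: getattr(cfg, f) for f in SimConfig.__dataclass_fields__}


def plot_scores(table: pd.DataFrame, x: str, path: str) -> None:
    """FDR / power panel plot over a varied parameter (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for metric, ax in zip(("fdr", "power"), axes):
        for method, sub in table.groupby("method"):
            agg = sub.groupby(x)[metric].mean()
            ax.plot(agg.index, agg.values, marker="o", label=method)
        ax.set_ylabel(metric)
    axes[0].axhline(0.10, ls="--", c="gray", lw=0.8)
    axes[1].set_xlabel(x)
    axes[0].legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
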