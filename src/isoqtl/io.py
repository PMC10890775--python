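"""Input/output and preprocessing for isoform-aware eQTL mapping.

Conventions used throughout the package:

* genotypes are stored samples x variants with dosages in [0, 2]
  (missing genotypes mean-imputed at load time);
* expression is stored isoforms x samples;
* genomic positions are 1-based internally; phenotype BED files use the
  usual 0-based half-open convention on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "IsoformExpressionSet",
    "CovariateMatrix",
    "CisWindow",
    "read_vcf",
    "read_phenotype_bed",
    "write_phenotype_bed",
    "read_covariates",
    "low_expression_filter",
    "inverse_normal_transform",
    "residualize",
    "cis_window",
    "align_samples",
    "maf",
    "testable_variants",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = [
    "gene_id",
    "n_isoforms",
    "best_variant",
    "best_isoform",
    "p_nominal",
    "p_adjusted",
    "q_value",
    "method",
]


@dataclass
class GenotypeMatrix:
    """Per-sample SNP dosages with variant coordinates.

    ``dosages`` is an (n samples x s variants) float array with values in
    [0, 2]; missing genotypes have already been replaced by the variant's
    mean dosage.  ``monomorphic`` flags variants with zero dosage variance,
    which are excluded from association testing.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray
    monomorphic: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.monomorphic is None:
            self.monomorphic = self.dosages.std(axis=0) == 0.0
        self.monomorphic = np.asarray(self.monomorphic, dtype=bool)
        # positions must be sorted within each chromosome so that cis-window
        # lookups can binary-search
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variant_ids[idx],
            self.chrom[idx],
            self.pos[idx],
            self.sample_ids,
            self.monomorphic[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        d = self.dosages[idx, :]
        return GenotypeMatrix(
            d, self.variant_ids, self.chrom, self.pos, self.sample_ids[idx],
            d.std(axis=0) == 0.0,
        )


@dataclass
class IsoformExpressionSet:
    """Isoform x sample expression with an isoform -> gene grouping.

    ``gene_tss`` maps gene id -> (chrom, 1-based TSS position, strand).
    """

    expr: np.ndarray
    isoform_ids: np.ndarray
    gene_of_isoform: np.ndarray
    sample_ids: np.ndarray
    gene_tss: dict
    # on-disk BED coordinates, kept so writing round-trips losslessly
    iso_chrom: np.ndarray = None
    iso_start: np.ndarray = None
    iso_end: np.ndarray = None
    iso_strand: np.ndarray = None

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.isoform_ids = np.asarray(self.isoform_ids, dtype=object)
        self.gene_of_isoform = np.asarray(self.gene_of_isoform, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.expr.shape != (len(self.isoform_ids), len(self.sample_ids)):
            raise ValueError("expr shape inconsistent with ids")

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def gene_ids(self) -> list:
        """Gene ids in first-appearance order."""
        return list(pd.unique(self.gene_of_isoform))

    def gene_expr(self, gene_id: str) -> np.ndarray:
        """(m x n) expression of the gene's isoforms."""
        mask = self.gene_of_isoform == gene_id
        if not mask.any():
            raise KeyError(gene_id)
        return self.expr[mask, :]

    def gene_isoform_ids(self, gene_id: str) -> np.ndarray:
        return self.isoform_ids[self.gene_of_isoform == gene_id]

    def take_samples(self, idx: np.ndarray) -> "IsoformExpressionSet":
        idx = np.asarray(idx)
        return IsoformExpressionSet(
            self.expr[:, idx], self.isoform_ids, self.gene_of_isoform,
            self.sample_ids[idx], self.gene_tss,
            self.iso_chrom, self.iso_start, self.iso_end, self.iso_strand,
        )


@dataclass
class CovariateMatrix:
    """Samples x covariates table (intercept is added where needed)."""

    values: np.ndarray
    covariate_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, c = self.values.shape
        if c >= n - 2:
            raise ValueError("too many covariates for the sample size")
        design = np.column_stack([np.ones(n), self.values])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate design is rank deficient with intercept")

    def take_samples(self, idx: np.ndarray) -> "CovariateMatrix":
        idx = np.asarray(idx)
        return CovariateMatrix(
            self.values[idx, :], self.covariate_ids,
            np.asarray(self.sample_ids, dtype=object)[idx],
        )


@dataclass
class CisWindow:
    """Variant indices of a gene's cis window (|pos - TSS| <= window_bp)."""

    gene_id: str
    variant_idx: np.ndarray
    window_bp: int

    @property
    def n_variants(self) -> int:
        return len(self.variant_idx)


# ---------------------------------------------------------------------------
# readers / writers


def read_vcf(path: str, region: str | None = None) -> GenotypeMatrix:
    """Load dosages from a VCF.

    Uses the DS FORMAT field when present, otherwise counts ALT alleles in
    GT.  Missing genotypes are replaced by the variant's mean dosage.
    ``region`` is ``"chrom"`` or ``"chrom:start-end"`` (1-based, inclusive)
    and is applied as a filter, so uncompressed files need no index.
    """
    import pysam

    rchrom, rstart, rend = None, None, None
    if region is not None:
        if ":" in region:
            rchrom, span = region.split(":", 1)
            s, e = span.split("-", 1)
            rstart, rend = int(s), int(e)
        else:
            rchrom = region

    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if len(samples) == 0:
        raise ValueError(f"VCF {path} has zero samples")

    dosages, vids, chroms, poss = [], [], [], []
    for rec in vf:
        if rchrom is not None and rec.chrom != rchrom:
            continue
        if rstart is not None and not (rstart <= rec.pos <= rend):
            continue
        row = np.empty(len(samples))
        for i, s in enumerate(samples):
            call = rec.samples[s]
            ds = call.get("DS") if "DS" in rec.format else None
            if ds is not None:
                row[i] = float(ds[0] if isinstance(ds, tuple) else ds)
            else:
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    row[i] = np.nan
                else:
                    row[i] = float(sum(1 for a in gt if a > 0))
        miss = np.isnan(row)
        if miss.all():
            row[:] = 0.0
        elif miss.any():
            row[miss] = row[~miss].mean()
        dosages.append(row)
        vids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)
    vf.close()

    if dosages:
        d = np.asarray(dosages).T
    else:
        d = np.empty((len(samples), 0))
    return GenotypeMatrix(d, vids, chroms, poss, samples)


def read_phenotype_bed(path: str) -> IsoformExpressionSet:
    """Read a grouped-phenotype BED: chrom, start, end, phenotype_id,
    group_id, strand, then one column per sample.

    BED coordinates are 0-based half-open; the TSS is start+1 on the plus
    strand and end on the minus strand (both 1-based).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 7:
        raise ValueError("phenotype BED needs 6 fixed columns plus samples")
    df.columns = [str(c).lstrip("#") for c in df.columns]
    fixed = ["chr", "start", "end", "phenotype_id", "group_id", "strand"]
    df.columns = fixed + list(df.columns[6:])
    if df["phenotype_id"].duplicated().any():
        dup = df["phenotype_id"][df["phenotype_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate phenotype_id {dup!r}")
    expr = df.iloc[:, 6:].to_numpy(dtype=float)
    if np.isnan(expr).any():
        raise ValueError("ragged or non-numeric expression values")

    tss = np.where(df["strand"] == "-", df["end"], df["start"] + 1)
    gene_tss = {}
    for g, c, t, st in zip(df["group_id"], df["chr"], tss, df["strand"]):
        gene_tss.setdefault(g, (str(c), int(t), str(st)))
    return IsoformExpressionSet(
        expr,
        df["phenotype_id"].to_numpy(),
        df["group_id"].to_numpy(),
        np.asarray(df.columns[6:], dtype=object),
        gene_tss,
        df["chr"].to_numpy(dtype=object),
        df["start"].to_numpy(dtype=np.int64),
        df["end"].to_numpy(dtype=np.int64),
        df["strand"].to_numpy(dtype=object),
    )


def write_phenotype_bed(es: IsoformExpressionSet, path: str) -> None:
    """Inverse of :func:`read_phenotype_bed` (lossless round trip)."""
    if es.iso_chrom is None:
        # reconstruct BED coordinates from the gene TSS
        chrom = np.empty(len(es.isoform_ids), dtype=object)
        start = np.empty(len(es.isoform_ids), dtype=np.int64)
        end = np.empty(len(es.isoform_ids), dtype=np.int64)
        strand = np.empty(len(es.isoform_ids), dtype=object)
        for i, g in enumerate(es.gene_of_isoform):
            c, t, st = es.gene_tss[g]
            chrom[i], strand[i] = c, st
            if st == "-":
                start[i], end[i] = t - 1, t
            else:
                start[i], end[i] = t - 1, t
    else:
        chrom, start, end, strand = es.iso_chrom, es.iso_start, es.iso_end, es.iso_strand
    df = pd.DataFrame({
        "#chr": chrom, "start": start, "end": end,
        "phenotype_id": es.isoform_ids, "group_id": es.gene_of_isoform,
        "strand": strand,
    })
    for j, s in enumerate(es.sample_ids):
        df[s] = es.expr[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path: str) -> CovariateMatrix:
    """Covariates TSV: first column sample id, remaining columns covariates."""
    df = pd.read_csv(path, sep="\t")
    return CovariateMatrix(
        df.iloc[:, 1:].to_numpy(dtype=float),
        np.asarray(df.columns[1:], dtype=object),
        df.iloc[:, 0].astype(str).to_numpy(),
    )


# ---------------------------------------------------------------------------
# preprocessing


def low_expression_filter(counts: np.ndarray, isoform_ids=None,
                          min_reads: int = 5, frac: float = 0.5) -> np.ndarray:
    """Keep isoforms unless ``min_reads`` or fewer reads map in at least
    ``frac`` of the samples.

    Returns the kept isoform ids (or row indices if ids are not given).
    """
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[None, :]
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    low_frac = (counts <= min_reads).mean(axis=1)
    keep = low_frac < frac
    if isoform_ids is None:
        return np.nonzero(keep)[0]
    return np.asarray(isoform_ids, dtype=object)[keep]


def inverse_normal_transform(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((rank - 0.5) / n) with
    average ranks for ties, applied along ``axis``."""
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(values, axis=axis).min() == 0:
        raise ValueError("constant values: inverse normal transform undefined")
    ranks = stats.rankdata(values, axis=axis)
    return stats.norm.ppf((ranks - 0.5) / n)


def residualize(values: np.ndarray, covariates: CovariateMatrix | np.ndarray,
                sample_axis: int = -1) -> np.ndarray:
    """OLS residuals of each row/column of ``values`` on [1, covariates].

    ``sample_axis`` identifies the axis of ``values`` indexed by samples.
    """
    cov = covariates.values if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n = cov.shape[0]
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    values = np.asarray(values, dtype=float)
    moved = np.moveaxis(values, sample_axis, 0) if values.ndim > 1 else values[:, None]
    if moved.shape[0] != n:
        raise ValueError("sample axis length does not match covariates")
    coef, *_ = np.linalg.lstsq(design, moved, rcond=None)
    resid = moved - design @ coef
    if values.ndim == 1:
        return resid[:, 0]
    return np.moveaxis(resid, 0, sample_axis)


def cis_window(gene_id: str, tss: tuple, geno: GenotypeMatrix,
               window_bp: int = 1_000_000) -> CisWindow:
    """Variants with |pos - TSS| <= window_bp (inclusive on both ends).

    ``tss`` is (chrom, 1-based position[, strand]).
    """
    chrom, pos = tss[0], int(tss[1])
    on_chrom = np.nonzero(geno.chrom == chrom)[0]
    if len(on_chrom) == 0:
        return CisWindow(gene_id, np.empty(0, dtype=int), window_bp)
    p = geno.pos[on_chrom]
    lo = np.searchsorted(p, pos - window_bp, side="left")
    hi = np.searchsorted(p, pos + window_bp, side="right")
    return CisWindow(gene_id, on_chrom[lo:hi], window_bp)


def align_samples(geno: GenotypeMatrix, expr: IsoformExpressionSet,
                  cov: CovariateMatrix | None = None):
    """Intersect sample ids and reorder all inputs to the genotype order.

    Returns (geno, expr[, cov]) restricted to the shared samples; raises if
    the intersection is empty, listing the set differences.
    """
    gset = set(geno.sample_ids)
    eset = set(expr.sample_ids)
    sets = [gset, eset]
    if cov is not None:
        sets.append(set(cov.sample_ids))
    common = set.intersection(*sets)
    if not common:
        raise ValueError(
            "no shared samples; genotype-only=%s expression-only=%s"
            % (sorted(gset - eset)[:5], sorted(eset - gset)[:5])
        )
    order = [s for s in geno.sample_ids if s in common]
    gidx = [list(geno.sample_ids).index(s) for s in order]
    eidx = [list(expr.sample_ids).index(s) for s in order]
    out = [geno.take_samples(np.asarray(gidx)), expr.take_samples(np.asarray(eidx))]
    if cov is not None:
        cidx = [list(cov.sample_ids).index(s) for s in order]
        out.append(cov.take_samples(np.asarray(cidx)))
    assert all(np.array_equal(out[0].sample_ids, o.sample_ids) for o in out[1:])
    return tuple(out)


def maf(geno: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per variant from mean dosage."""
    f = geno.dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def testable_variants(geno: GenotypeMatrix, maf_min: float = 0.01) -> np.ndarray:
    """Boolean mask of variants retained for association testing
    (polymorphic and MAF >= maf_min)."""
    return (~geno.monomorphic) & (maf(geno) >= maf_min)


# ---------------------------------------------------------------------------
# results


def write_results(results, path: str) -> None:
    """Write per-gene results as a TSV sorted by gene_id.

    ``results`` is a DataFrame or an iterable of objects with the
    RESULT_COLUMNS attributes (e.g. :class:`isoqtl.perm.GeneResult`).
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results],
            columns=RESULT_COLUMNS,
        )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results missing columns {missing}")
    df = df[RESULT_COLUMNS].sort_values("gene_id", kind="mergesort")
    df["best_isoform"] = df["best_isoform"].fillna("NA")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                     dtype=str)
    for col in ("n_isoforms", "p_nominal", "p_adjusted", "q_value"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
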