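# Methods

## Problem setting

A gene produces $m$ mature transcript isoforms; bulk RNA-seq quantification
gives an isoform × sample expression matrix. A *cis*-eQTL analysis asks, for
every SNP within a window around the gene's transcription start site (TSS),
whether the SNP's dosage (0/1/2) is associated with expression. Collapsing
isoforms to one gene value (sum, mean, or first principal component) before
testing is standard but throws away signal: a splice QTL shifts expression
*between* isoforms, so opposite-signed effects cancel in the sum. `isoqtl`
implements the isoform-aware alternatives and the machinery needed to call
eGenes at a controlled false discovery rate, plus a generative simulator so
all of it can be validated against known truth.

## Association tests

All tests operate per (gene, SNP) with $n$ samples, dosage vector $x$ and
isoform matrix $Y$ ($n \times m$ in the formulas below; stored $m \times n$
internally).

**Per-isoform OLS.** Two-sided t-test on the slope of $y_i \sim 1 + x$ with
$n-2$ residual df (reduced by the covariate count when expression was
residualized upstream). p-values are floored at 1e-300 so logs stay finite.

**Aggregation.** Fisher's method sums $-2\log p_i$ against $\chi^2_{2m}$;
it is exact under independence but anti-conservative when isoforms (hence
their p-values) are correlated. The Cauchy combination test
$T = \sum_i \omega_i\tan([0.5-p_i]\pi)$ with $p = 1/2 - \arctan(T)/\pi$
(uniform weights by default) is insensitive to dependence. Numerical guard:
for $p_i < 10^{-15}$ the tangent is replaced by its asymptote
$1/(p_i\pi)$, and for $T > 10^{15}$ the arctan by $1/(T\pi)$ — the exact
expressions overflow double precision. The minimum rule returns $\min_i p_i$
with *no* correction; it is included because, applied after per-isoform
permutation adjustment, it is a tempting-but-wrong recipe whose inflated
gene-level FDR the benchmark quantifies.

**Wilks–Bartlett.** The multivariate regression $Y \sim 1 + x$ versus the
intercept-only model gives $\Lambda^{2/n} = |\hat\Sigma|/|\hat\Sigma_i|$
from the residual cross-product matrices; Bartlett's statistic
$-(n-2-m/2)\log\Lambda^{2/n}$ is compared to $\chi^2_m$. Both models include
an intercept. The determinant ratio is computed with a rank-one determinant
update ($1 - u^\top S^{-1} u$), never by forming two determinants, so the
ratio is exactly in $(0, 1]$ by construction. Collinear isoforms make
$\hat\Sigma_i$ singular and raise an error. The test assumes residual rows
independent across samples — the assumption that correlated non-genetic
structure violates, which is why the benchmark shows its FDR exploding.

**Multiple-regression F-test.** The regression direction is inverted: the
SNP is the response, $x \sim 1 + Y$, and the nested F-test against
$x \sim 1$ uses $F = \frac{(RSS_i - RSS_f)/m}{RSS_f/(n-m-1)} \sim
F(m,\,n-m-1)$. The conventional df pair is used. Collinear isoform columns
are dropped (QR with column pivoting) with the df adjusted accordingly.

**PCA collapse.** `pca1` scores samples on the first principal component of
the row-centered isoform matrix; the sign is fixed so the largest-magnitude
loading is positive, making results reproducible across LAPACK builds.

## Permutation adjustment and FDR

Within one gene, cis-SNP tests are strongly dependent through linkage
disequilibrium, so the per-gene multiplicity correction is a permutation
test on the gene's *minimum* p-value. Each of $R$ replicates permutes the
phenotype's sample order — one **shared** permutation applied to all $m$
isoforms, preserving their correlation under the null (independent
per-isoform permutation is a correctness bug; a dedicated test shows it
miscalibrates on correlated nulls) — and recomputes the minimum over the
method's whole search space. The direct estimate $(r+1)/(R+1)$ is kept for
diagnostics; the reported adjusted p-value is the CDF of a Beta$(a,b)$
distribution fitted to the $R$ null minima by maximum likelihood (Newton
iterations on the two shape parameters via the sufficient statistics
$\overline{\log p}$ and $\overline{\log(1-p)}$; method-of-moments
initialization and fallback; gradient tolerance 1e-8). Default $R = 1000$
($R = 500$ in the benchmark), minimum 50 for a stable fit. The
effective-degrees-of-freedom refinement some tools add to the Beta scheme is
deliberately not implemented; the plain two-parameter fit is the modeled
procedure.

Permutations for a gene come from a counter-based substream seeded by
(master seed, CRC32 of the gene id), so results are independent of gene
processing order and bit-reproducible.

Across genes, Storey–Tibshirani q-values are computed from the adjusted
p-values: $\hat\pi_0$ from the $\lambda$-grid $\{0.05,\dots,0.95\}$ with a
cubic least-squares smoother evaluated at $\lambda \to 1$, clamped to
$(0,1]$. Two conservative fallbacks set $\hat\pi_0 = 1$ (reducing the
q-value to Benjamini–Hochberg): fewer than 100 tests, or **no p-value above
the top of the grid**. The latter matters: uncorrected minimum aggregation
(min-iso) produces gene p-values that are minima of $m$ uniforms, leaving
the right tail empty; the smoother would estimate $\hat\pi_0 \approx 0$ and
call every gene (reference q-value implementations error out here). With
the BH fallback the min-iso pipeline instead shows the genuine, moderate
(~2×) FDR inflation that motivates warning against it. If the smoother goes
nonpositive while the tail is populated, the plug-in estimate at
$\lambda = 0.95$ is used. eGenes are called at $q \le 0.10$.

## Simulator

Per gene, expression is $Y = \sum_j \beta_j x_j^\top + U + \varepsilon$
(isoforms × samples) under a unit variance budget
$\sigma_g^2 + \sigma_h^2 + \sigma_e^2 = 1$:

* A gene is null ($\sigma_g^2 = 0$) with probability 0.5; otherwise
  $k \in \{1,2,3\}$ causal SNPs are drawn uniformly from the window and
  $\sigma_g^2$ is split across them by a symmetric Dirichlet.
* Causal dosage columns are standardized, so $\sigma_{gj}^2$ is the expected
  variance explained per isoform; $\beta_j \sim N(0, \sigma_{gj}^2\Phi_j)$
  where $\Phi_j$ is a random correlation matrix whose off-diagonal
  magnitudes are Uniform(0.2, 0.8) with negative sign with probability
  `negpct`, projected to the nearest positive-semidefinite correlation
  matrix (alternating eigenvalue-clipping / unit-diagonal restoration, with
  shrinkage toward the identity if the projection stalls). High `negpct`
  makes isoform effects cancel in the summed phenotype — the mechanism
  behind the power collapse of gene-level methods.
* $U = \sigma_h L_V Z L_W^\top$ with $Z$ iid standard normal: a matrix
  normal with isoform correlation $V$ (as $\Phi$, `negpct` 0.5) and sample
  correlation $W$ (block-exchangeable, 4 equal blocks, within-block
  $\rho = 0.5$, unit diagonal), so each entry has variance $\sigma_h^2$.
  $U$ models non-cis structure shared across isoforms and samples
  (environment, trans-regulation, batches).
* $\varepsilon$ is iid $N(0, \sigma_e^2)$.

Genotypes are synthetic diploid dosages: each haplotype is a stationary
AR(1) Gaussian series (lag-one correlation 0.7 between adjacent sites)
thresholded at a per-site minor-allele frequency drawn Uniform(0.05, 0.5);
dosage = sum of two haplotypes; 200 sites evenly spaced over the 100 kb cis
window. Defaults (87 samples, 4 isoforms per gene, 50% null genes,
$\sigma_g^2 = 0.05$, $\sigma_h^2 = 0$, `negpct` = 0.5) are the benchmark's
study conditions.

**What the simulator does not emulate.** Real LD is blocky and long-ranged,
not AR(1), so causal-SNP effects never co-add at a linked tested SNP here;
expression is Gaussian rather than count-derived; isoform counts per gene
are fixed at $m$; there are no covariates, population structure, or
mapping/quantification noise. Passing benchmarks therefore validate the
statistical machinery under the stated generative model, not performance on
real data.

## Numerical and design choices

* Genotype orientation samples × variants, expression isoforms × samples;
  positions 1-based internally, BED 0-based half-open on disk; TSS is
  strand-aware (start+1 on +, end on −).
* Missing genotypes mean-imputed; monomorphic and MAF < 0.01 variants
  excluded from testing (configurable).
* cis window default 1 Mb for data mapping, 100 kb in the simulator.
* Inverse-normal transform uses the rankit offset $(r - 0.5)/n$ with
  average ranks for ties.
* Best-pair ties break to the smallest variant index, then smallest isoform
  index.
* All p-values floored at 1e-300.
* Vectorized passes reduce min-p searches to max-|correlation| (or max-F /
  min-ratio) before any distribution-function call, which is what keeps a
  400-gene × 200-SNP × 500-permutation benchmark in tens of seconds.

## Benchmark scale and known limitations

The shipped benchmark uses 400 genes, one replicate, and 500 permutations —
sizes chosen so the whole study runs in well under a minute while leaving
binomial noise of a few percentage points on empirical FDR and power; the
scripts and tests report single-seed values, and the test suite's fixed-seed
assertions sit close to their tolerance edges for the power and
min-iso-inflation checks (see the test docstrings). Under this generative
model the realized per-gene effect size $\|\beta\|^2$ is itself random
(chi-square-type draws split across unlinked causal SNPs), so a fraction of
non-null genes is intrinsically undetectable at any threshold: an oracle
that knows the causal SNP tops out near 91% detection at
$\sigma_g^2 = 0.2$ and 69% at $\sigma_g^2 = 0.1$ at benchmark sample size,
which bounds every method's measurable power. The Wilks–Bartlett FDR
"explosion" under shared non-cis effects saturates at the simulated null
fraction (50%) because essentially every gene is called.

Other limitations: no GLM/count models, no multi-SNP joint tests, no
hierarchical or stage-wise FDR alternatives, no covariate inference (a
covariate matrix is residualized out if supplied), and no support for
overlapping cis windows sharing genotype simulation.
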