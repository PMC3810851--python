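# Methods

## Model

Let `Z = (Z_u, Z_t)` be the association Z-scores at untyped and typed SNPs
in a region.  Under the null hypothesis of no association, `Z` is
(asymptotically) multivariate normal with mean zero and covariance equal to
the correlation matrix of the genotype dosages, i.e. the LD matrix `Σ`.
This holds regardless of how the Z-scores were produced — linear-regression
Wald statistics, meta-analysis statistics, or family-based statistics —
because only the null correlation structure enters.  Writing `Σ_tt` for the
typed–typed block and `Σ_ut` for the untyped–typed block, the conditional
distribution of `Z_u` given `Z_t` has mean and variance

    E[Z_u | Z_t]   = Σ_ut Σ_tt⁻¹ Z_t
    Var[Z_u | Z_t] = Σ_uu − Σ_ut Σ_tt⁻¹ Σ_tu

The imputed statistic is the conditional mean, computed with a ridge term:

    Ẑ_u = Σ_ut (Σ_tt + λI)⁻¹ Z_t,
    r²_pred = diag( Σ_ut (Σ_tt + λI)⁻¹ Σ_tu ).

`r²_pred` is the null variance of `Ẑ_u`: the fraction of the unit null
variance of the true statistic that the typed SNPs recover.  It is the
natural quality score for a conditional-mean imputer — 1 for a perfectly
tagged SNP, 0 for a SNP carrying no LD information — and, at λ=0 and with a
positive semidefinite joint `Σ`, it is bounded in [0, 1] by the Schur
complement, and can only grow as predictors are added (a projection).

`Σ` is estimated as the Pearson correlation of 0/1 allele indicators across
the phased haplotypes of a reference panel.  Haplotype indicators rather
than diploid dosages are used because phased panels expose the
finer-grained estimator; under Hardy–Weinberg equilibrium the dosage
correlation has the same expectation.

### Reported Z convention

The reported value is the raw conditional mean, which is *shrunken*: its
null variance is `r²_pred`, not 1.  An optional rescaled output
`Ẑ_u / √r²_pred` restores unit null variance (both conventions exist in the
literature; the raw mean is the literal conditional expectation, and the
rescaled variant inflates noise at poorly tagged SNPs, which is why it is
opt-in).  P-values in the output are always the two-sided normal tail of
the reported Z.

### Windows

Typed SNPs are partitioned, per chromosome, into consecutive *prediction
windows* of `pred_size` SNPs (default 100; the last window may be shorter).
Each untyped SNP is assigned to exactly one prediction window by a
half-open positional rule keyed on the first typed SNP of each window core
(untyped SNPs before the first typed SNP join the first window).  The
predictor set for a window is its core plus `flank_size` typed SNPs on each
side (default 250 per side), truncated at chromosome ends.  When the
extended window spans all typed SNPs the result coincides exactly with the
one-shot full-matrix conditional mean; otherwise windowing is a locality
approximation that trades the (negligible) influence of distant SNPs for
linear-time processing.  The defaults are this implementation's own choice:
prediction windows small enough that the flanks dominate, flanks wide
enough to exhaust useful LD in typical genome-wide data.

### Numerical choices

- The solve uses a Cholesky factorisation of `Σ_tt + λI`; no explicit
  inverse is ever formed.
- λ (``lam``) defaults to 1e-3 on the correlation scale.  Finite panels make
  `Σ_tt` ill-conditioned (in the limit, duplicated haplotype columns make it
  singular); 1e-3 stabilises the solve while perturbing well-conditioned
  answers below output precision.  With λ>0 every `r²_pred` is strictly
  smaller than its λ=0 value — quality is never overstated.
- With λ=0 a near-singular block (smallest eigenvalue < 1e-10) is refused
  with advice to set λ>0 or prune.
- If a window's factorisation still fails, typed pairs with |r| > 0.999 are
  pruned, deterministically keeping the lower-position SNP, and the window
  is retried.
- Targets with `r²_pred` below ``min_r2pred`` (default 0.3) are reported
  with status ``skipped`` and no Z: low-information imputations are more
  misleading than missing values.  The threshold is recorded in the output
  header.
- `r²_pred` values are clipped to [0, 1] for reporting; tiny negative
  round-off is clipped to 0.

### Harmonisation

Statistics and panel must share one allele orientation before `Z_t` and `Σ`
can be combined.  The canonical orientation is the panel's alt allele:
records whose effect allele is the panel ref allele get `Z` negated
(`allele_swap`); records matching only after reverse-complementing both
alleles are strand-flipped first.  A/T and C/G SNPs are strand-ambiguous
(reverse complement equals allele swap) and are dropped unless
``keep_ambiguous`` is set.  Matching is by (chromosome, position) with
``chr`` prefixes stripped; rsIDs are ignored because they drift across
builds.  Records at positions absent from the panel cannot enter the LD
matrix and are counted and ignored.  The whole pipeline is invariant to
relabeling input alleles (flip labels and Z sign): the harmonised `Z_t` and
the rows of `Σ_ut` flip coherently, leaving every imputed value unchanged —
this is asserted in the test suite.

### Pre-computed correlation tables

Because the panel enters only through the per-window blocks `Σ_tt` and
`Σ_ut`, these can be computed once and cached (one file: JSON text header
with panel checksum, window parameters and block offsets, followed by raw
float64 blocks).  Imputation from the cache is bit-identical to imputation
from the haplotypes; a cache whose checksum or window parameters disagree
with the current run is refused.

## Synthetic data

The simulator reproduces the statistical structure of a
summary-statistic-imputation accuracy experiment at desk scale.

**Panel.** Founder haplotypes (default 2) get independent per-site alleles
with U-shaped frequencies on (0.01, 0.5), redrawn where all founders agree.
LD blocks are delimited by shared breakpoints: each site opens a new block
with probability ``ld_decay`` (default 0.175); within a block every
haplotype copies one uniformly drawn founder; each allele is then flipped
with probability ``mut_rate`` (default 0.01).  This yields genuinely blocky
LD — within-block |r| ≈ 0.96, independence across blocks — with mean
adjacent |r| ≈ 0.80 at the defaults (measured over seeds during a one-time
calibration).  ``ld_decay = 1`` gives independent sites; ``ld_decay = 0``
makes every haplotype a copy of one founder.

**Study.** Each subject's genotype is the sum of two haplotypes drawn
uniformly with replacement from the panel pool, so study LD equals
reference LD by construction — deliberately isolating imputation error from
population mismatch, the regime in which summary-statistic imputation is
claimed to work; a mismatched study can be produced by simulating a second
panel.  The phenotype is `Σ β_j g_j + ε` with ``n_causal`` (default 10)
causal SNPs and the βs jointly scaled so the causal SNPs explain ``h2``
(default 0.3) of the phenotypic variance.

**Z-scores.** Per-SNP simple-regression Wald statistics: the t statistic of
the dosage–phenotype correlation mapped exactly (via log tail
probabilities) to a standard-normal quantile.  Zero-variance SNPs are
flagged NaN and excluded.

**Masking.** Either a missing-at-random fraction (default 5%) or an
explicit target list.  With ``mask_ld_threshold`` set, a SNP is masked only
while it retains a typed proxy with |r| at or above the threshold, and
masking never strands an already-masked SNP without a proxy — emulating the
imputation of well-tagged SNPs (the list of imputed index SNPs in a dense
panel) rather than arbitrary ones.

**Scoring.** The squared Pearson correlation between imputed and true
(full-data) Z-scores across masked SNPs, pooled over replicates.  Note this
metric is invariant to affine shifts of the imputed values: it measures
tracking, not bias.  Per-SNP absolute errors are reported alongside.

### What the simulator does and does not emulate

It reproduces: block LD with realistic strength, matched study/reference
sampling, polygenic quantitative-trait signal, exact single-SNP test
statistics, MAR masking with or without proxy constraints.  It does not
reproduce: realistic allele-frequency spectra at the 2-founder default
(frequencies cluster near 0.5 because every site follows the founder-usage
indicator; raising ``n_founder`` restores frequency spread but weakens
attainable LD), long-range LD, population stratification, relatedness
within the study, genotyping error, or imperfect study/reference matching.
Passing accuracy tests on these data therefore demonstrates correctness of
the conditional-mean machinery under its stated assumptions, not
performance on mismatched or admixed real cohorts.

### Problem sizes

The standard accuracy configuration is 1,000 haplotypes × 2,000 SNPs,
2,000 subjects, 10 causal SNPs at h² = 0.3, 100 masked SNPs with a
|r| ≥ 0.8 proxy, pooled over 25 replicates (~20 s total); the null
calibration uses 300 haplotypes × 300 SNPs, 500 subjects and 500 phenotype
permutations (~4 s).  These sizes give stable estimates (≈2,500 pooled
pairs; Monte-Carlo SE on pooled r² well below 0.01) while keeping the whole
suite interactive.

## Known limitations

- Two-sided-normal p↔Z conversion only; χ²(1df) or other non-normal input
  statistics must be converted upstream.
- Biallelic SNVs only; no indels, no multiallelics.
- No liftover, no allele-frequency-based strand resolution for ambiguous
  SNPs, no cross-chromosome windows, no special handling of long-range LD
  regions (e.g. MHC), where genotype imputation remains preferable.
- The imputed statistics are shrunken conditional means; downstream users
  who need calibrated test statistics should use the rescaled output or
  account for `r²_pred`.
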