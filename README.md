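# zimpute

Direct imputation of GWAS summary statistics (Z-scores) at untyped SNPs.

Most genotype-imputation pipelines (IMPUTE2-style HMMs, multinomial
haplotype models) need subject-level genotypes, which consortia often do not
release, and they are computationally heavy.  `zimpute` skips the genotype
step entirely: it imputes the *association statistics* themselves.  Under
the null hypothesis the vector of per-SNP Z-scores is multivariate normal
with zero mean and covariance equal to the local LD correlation matrix, so
the statistic at an unmeasured SNP can be predicted by the conditional
expectation

```
Ẑ_u = Σ_ut (Σ_tt + λI)⁻¹ Z_t
```

where `Z_t` are the measured-SNP Z-scores, `Σ_tt` and `Σ_ut` are
typed–typed and untyped–typed correlation blocks estimated from a phased
reference panel (e.g. 1000 Genomes-style haplotypes), and `λ` is a small
ridge term guarding against finite-panel ill-conditioning.  The per-SNP
imputation quality

```
r²_pred = diag( Σ_ut (Σ_tt + λI)⁻¹ Σ_tu )
```

is the null variance of the imputed statistic (1 = perfectly tagged,
0 = no information).  The genome is processed in sliding *prediction
windows* of typed SNPs; each window's predictors are its own typed SNPs
plus flanking typed SNPs on both sides (the *extended window*).  Because
only the null correlation structure enters, the method applies equally to
statistics from unrelated-subject studies and from family/pedigree designs.

The package is aimed at statistical geneticists who have a summary-statistics
file and a reference panel but no subject-level genotypes, and at method
developers who need a controlled test bed: a synthetic-data subsystem
generates block-LD haplotype panels, quantitative-trait studies, association
Z-scores and missing-at-random masks.

## Worked example

Simulate a study, hold out 5% of SNPs, impute them back, and score the
result:

```sh
zimpute simulate --out sim --n-hap 200 --n-snp 300 --n-subj 300 \
    --n-causal 4 --seed 3
zimpute impute --sumstats sim.sumstats.tsv \
    --ref-hap sim.hap --ref-legend sim.legend \
    --out imp --pred-size 50 --flank-size 50
zimpute evaluate --imputed imp.tsv --truth sim.truth.tsv
```

The impute step prints a fit summary such as

```
Direct summary-statistic imputation
===============================================
panel variants              300
reference haplotypes        200
typed                       285
imputed                      15
skipped (low r2pred)          0
off-panel records             0
windows                       6
-----------------------------------------------
pred_size                                    50
flank_size                                   50
lam                                       0.001
min_r2pred                                  0.3
keep_ambiguous                            False
rescale                                   False
-----------------------------------------------
r2pred (targets)     0.674 0.971 0.978 0.983 1.000  (min q25 med q75 max)
===============================================
```

(285 of the 300 panel SNPs arrived with observed statistics; the 15 held-out
SNPs were all imputed, none fell below the `r2pred` reporting threshold, and
the median imputation quality was 0.978.)  The evaluate step then prints

```
r2 = 0.9955 over 15 SNPs
mean |error| = 0.0822
```

i.e. the imputed Z-scores explain 99.6% of the variance of the held-out true
Z-scores.  The same pipeline is available as a library:

```python
from zimpute import DirectImputation

model = DirectImputation.from_files(
    "sim.sumstats.tsv", hap="sim.hap", legend="sim.legend",
    pred_size=50, flank_size=50,
)
res = model.fit()
print(res.summary())
df = res.frame()   # chrom, pos, a1, a2, z, p, r2pred, status per variant
```

## Layout

- `src/zimpute/sumstats.py` — summary-statistics I/O, p↔Z conversion
- `src/zimpute/panel.py` — VCF / hap+legend panels, LD blocks, correlation cache
- `src/zimpute/harmonize.py` — allele/strand alignment of statistics to the panel
- `src/zimpute/impute.py` — windows, conditional-mean solver, model/results API
- `src/zimpute/simulate.py` — synthetic panels, studies, masking, evaluation
- `src/zimpute/cli.py` — `zimpute impute | simulate | evaluate`

See `docs/methods.md` for the model, its assumptions and the design choices.
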